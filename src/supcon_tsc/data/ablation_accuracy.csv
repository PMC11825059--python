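dataset,without-SupCon,with-SupCon
ArticularyWordRecognition,0.97,0.98
AtrialFibrillation,0.266,0.467
BasicMotions,1.0,1.0
CharacterTrajectories,0.995,0.997
Cricket,0.986,1.0
DuckDuckGeese,0.44,0.54
EigenWorms,0.862,0.885
Epilepsy,0.985,0.993
EthanolConcentration,0.277,0.231
FaceDetection,0.559,0.565
HandMovementDirection,0.378,0.338
FingerMovements,0.52,0.61
Libras,0.872,0.85
LSST,0.662,0.657
MotorImagery,0.59,0.59
NATOPS,0.911,0.894
PenDigits,0.986,0.993
PEMS-SF,0.843,0.861
Handwriting,0.624,0.566
Heartbeat,0.741,0.746
InsectWingbeat,0.665,0.667
JapaneseVowels,0.983,0.987
PhonemeSpectra,0.313,0.322
SpokenArabicDigits,0.993,0.995
RacketSports,0.848,0.875
SelfRegulationSCP1,0.703,0.730
SelfRegulationSCP2,0.488,0.55
StandWalkJump,0.333,0.6
UWaveGestureLibrary,0.837,0.812
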