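dataset,SupCon-TSC,TapNet,MTEX-CNN,XCM,MLSTM-FCN,WEASEL-MUSE,LCEM,XGBM,RFM
ArticularyWordRecognition,0.98,0.964,0.913,0.977,0.986,0.993,0.993,0.99,0.99
AtrialFibrillation,0.467,0.333,0.333,0.467,0.133,0.267,0.467,0.40,0.333
BasicMotions,1,1,0.68,1,1,1,1,1,1
CharacterTrajectories,0.997,0.997,0.974,0.995,0.993,0.990,0.979,0.983,0.985
Cricket,1,0.958,0.78,0.986,0.986,0.986,0.986,0.972,0.986
DuckDuckGeese,0.54,0.44,0.4,0.3,0.579,0.575,0.375,0.40,0.40
EigenWorms,0.885,0.86,0.419,0.526,0.908,0.89,0.527,0.55,1
Epilepsy,0.993,0.978,0.94,0.94,0.985,0.993,0.986,0.978,0.986
EthanolConcentration,0.231,0.231,0.251,0.32,0.254,0.316,0.372,0.422,0.433
FaceDetection,0.565,0.55,0.50,0.58,0.556,0.545,0.614,0.629,0.614
HandMovementDirection,0.338,0.37,0.432,0.405,0.472,0.378,0.649,0.541,0.50
FingerMovements,0.61,0.52,0.61,0.59,0.579,0.54,0.59,0.53,0.56
Handwriting,0.566,0.37,0.17,0.4,0.544,0.531,0.287,0.267,0.267
Heartbeat,0.746,0.752,0.721,0.72,0.731,0.727,0.761,0.693,0.80
InsectWingbeat,0.667,0.208,0.105,0.105,0.105,,0.228,0.237,0.224
JapaneseVowels,0.987,0.965,0.951,0.986,0.992,0.978,0.978,0.968,0.970
Libras,0.85,0.877,0.6,0.77,0.883,0.894,0.772,0.767,0.783
LSST,0.657,0.55,0.57,0.51,0.601,0.628,0.652,0.633,0.612
MotorImagery,0.59,0.53,0.5,0.5,0.529,0.50,0.60,0.46,0.55
NATOPS,0.894,0.93,0.75,0.71,0.905,0.883,0.916,0.90,0.911
PenDigits,0.993,0.98,0.896,0.98,0.99,0.969,0.977,0.951,0.951
PEMS-SF,0.861,0.77,0.838,0.83,0.809,,0.942,0.983,0.983
PhonemeSpectra,0.322,0.19,0.08,0.13,0.266,0.19,0.288,0.187,0.222
RacketSports,0.875,0.83,0.723,0.78,0.875,0.914,0.941,0.928,0.921
SelfRegulationSCP1,0.73,0.75,0.767,0.860,0.829,0.744,0.839,0.829,0.826
SelfRegulationSCP2,0.55,0.55,0.50,0.55,0.494,0.522,0.55,0.483,0.478
SpokenArabicDigits,0.995,0.983,0.986,0.995,0.994,0.982,0.973,0.970,0.968
StandWalkJump,0.6,0.47,0.4,0.533,0.6,0.333,0.40,0.333,0.467
UWaveGestureLibrary,0.812,0.89,0.69,0.88,0.881,0.903,0.897,0.894,0.907
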