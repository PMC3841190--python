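{
 "6": 0.002,
 "7": 0.007,
 "8": 0.014,
 "9": 0.785,
 "10": 0.033,
 "11": 0.608,
 "12": 0.483,
 "13": 0.8,
 "14": 0.996,
 "15": 0.996,
 "16": 0.996,
 "17": 0.996,
 "18": 0.996,
 "19": 0.996,
 "20": 0.996,
 "21": 0.996,
 "22": 0.996,
 "23": 0.996,
 "24": 0.996,
 "25": 0.996,
 "26": 0.996,
 "27": 0.996
}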