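{
  "description": "SYNTHETIC stand-in for the published curvilinearity-correcting MMSE normalisation table (raw 0-30 to normalised 0-100). The published table is not reproduced here; this monotone lookup preserves its qualitative shape: score differences near the ceiling of the raw scale are expanded on the normalised scale, differences in the mid-range are compressed. Endpoints map 0->0 and 30->100.",
  "version": "1.0-synthetic",
  "table": {
    "0": 0.0, "1": 3.0, "2": 6.0, "3": 9.0, "4": 12.0, "5": 15.0,
    "6": 18.0, "7": 21.0, "8": 24.0, "9": 27.0, "10": 30.0,
    "11": 33.0, "12": 36.0, "13": 39.0, "14": 42.0, "15": 45.0,
    "16": 48.0, "17": 51.0, "18": 54.0, "19": 57.0, "20": 60.0,
    "21": 62.0, "22": 64.0, "23": 66.0, "24": 68.0, "25": 70.0,
    "26": 72.0, "27": 76.0, "28": 80.0, "29": 87.0, "30": 100.0
  }
}
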