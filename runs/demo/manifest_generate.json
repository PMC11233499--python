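{
  "config_hash": "23de8a9a82b626b5",
  "elapsed_seconds": 2.098,
  "inputs": {},
  "outputs": {
    "compounds.csv": "520a9dfe177dcf93",
    "ground_truth.json": "751da310327300cc",
    "measurements.csv": "7ae75be570c83ad3"
  },
  "seed": 369571992,
  "stage": "generate"
}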