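{
  "ambulatory_trigger_icds": {
    "name": "ambulatory_trigger_icds",
    "prefixes": ["I21", "I25", "I42", "I48"],
    "ranges": [],
    "procedures": []
  },
  "ambulatory_trigger_procedures": {
    "name": "ambulatory_trigger_procedures",
    "prefixes": [],
    "ranges": [],
    "procedures": ["BNP", "ECHO", "CATH", "ERGO", "CHAGAS_SERO"]
  },
  "mortality_set": {
    "name": "mortality_set",
    "prefixes": ["B57", "I48", "I49", "I51"],
    "ranges": [["I05", "I08"], ["I21", "I25"], ["I34", "I39"], ["I42", "I44"]],
    "procedures": []
  }
}
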