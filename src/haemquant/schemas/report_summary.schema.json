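{
  "title": "haemquant study report summary",
  "type": "object",
  "required": [
    "config_hash",
    "seed",
    "n_scans",
    "n_observers",
    "n_sessions",
    "observer_model_note",
    "mean_volume_cm3",
    "tables"
  ],
  "properties": {
    "config_hash": {"type": "string"},
    "seed": {"type": "integer"},
    "n_scans": {"type": "integer", "minimum": 0},
    "n_observers": {"type": "integer", "minimum": 1},
    "n_sessions": {"type": "integer", "minimum": 1},
    "observer_model_note": {"type": "string"},
    "mean_volume_cm3": {"type": "object"},
    "tables": {"type": "array", "items": {"type": "string"}}
  }
}
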