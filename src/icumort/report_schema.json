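{
 "type": "object",
 "required": ["seed", "config", "cohort", "models", "standardized_comparison",
              "random_effects", "endogeneity", "loa", "ranking", "failures"],
 "properties": {
  "seed": {"type": "integer"},
  "config": {
   "type": "object",
   "required": ["n_patients", "n_sites", "base_terms", "cv_k", "cv_reps"],
   "properties": {
    "n_patients": {"type": "integer"},
    "n_sites": {"type": "integer"},
    "base_terms": {"type": "array", "items": {"type": "string"}},
    "cv_k": {"type": "integer"},
    "cv_reps": {"type": "integer"}
   }
  },
  "cohort": {
   "type": "object",
   "required": ["n", "n_sites", "mortality", "ventilated"],
   "properties": {
    "n": {"type": "integer"},
    "n_sites": {"type": "integer"},
    "mortality": {"type": "number"},
    "ventilated": {"type": "number"}
   }
  },
  "models": {"type": "object"},
  "standardized_comparison": {"type": "object"},
  "random_effects": {"type": "object"},
  "endogeneity": {"type": "object"},
  "loa": {"type": "object"},
  "ranking": {
   "type": "object",
   "properties": {
    "aic": {"type": "array", "items": {"type": "string"}},
    "bic": {"type": "array", "items": {"type": "string"}}
   }
  },
  "failures": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["model", "error"],
    "properties": {"model": {"type": "string"}, "error": {"type": "string"}}
   }
  }
 }
}
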