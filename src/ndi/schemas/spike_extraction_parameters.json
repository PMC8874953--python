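{
 "fields": {
  "filter": {
   "kind": "object",
   "required": true
  },
  "min_width_ms": {
   "kind": "number",
   "required": false
  },
  "refractory_ms": {
   "kind": "number",
   "required": true
  },
  "threshold": {
   "kind": "object",
   "required": true
  },
  "window": {
   "kind": "object",
   "required": true
  }
 },
 "name": "spike_extraction_parameters",
 "superclasses": [
  "ndi_document",
  "ndi_app"
 ],
 "version": 1
}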