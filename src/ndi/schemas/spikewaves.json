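{
 "fields": {
  "n_spikes": {
   "kind": "integer",
   "required": true
  },
  "sample_rate": {
   "kind": "number",
   "required": true
  },
  "window": {
   "kind": "object",
   "required": true
  }
 },
 "name": "spikewaves",
 "superclasses": [
  "ndi_document",
  "ndi_epochid",
  "ndi_app"
 ],
 "version": 1
}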