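{
 "fields": {
  "responses": {
   "kind": "list",
   "required": true
  }
 },
 "name": "stimulus_response",
 "superclasses": [
  "ndi_document"
 ],
 "version": 1
}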