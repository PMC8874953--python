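{
 "fields": {
  "description": {
   "kind": "string",
   "required": false
  },
  "local_id": {
   "kind": "string",
   "required": true
  }
 },
 "name": "subject",
 "superclasses": [
  "ndi_document"
 ],
 "version": 1
}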