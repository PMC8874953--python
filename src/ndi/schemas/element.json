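{
 "fields": {
  "direct": {
   "kind": "integer",
   "required": true
  },
  "element_kind": {
   "kind": "string",
   "required": true
  },
  "name": {
   "kind": "string",
   "required": true
  },
  "reference": {
   "kind": "integer",
   "required": true
  },
  "type": {
   "kind": "string",
   "required": true
  }
 },
 "name": "element",
 "superclasses": [
  "ndi_document"
 ],
 "version": 1
}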