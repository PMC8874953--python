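{
 "fields": {
  "depends_on": {
   "kind": "list",
   "required": true
  },
  "id": {
   "kind": "string",
   "required": true
  },
  "schema": {
   "kind": "object",
   "required": true
  },
  "session_id": {
   "kind": "string",
   "required": true
  },
  "timestamp": {
   "kind": "string",
   "required": true
  }
 },
 "name": "ndi_document",
 "superclasses": [],
 "version": 1
}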