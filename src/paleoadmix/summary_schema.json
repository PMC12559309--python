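{
  "title": "paleoadmix analysis summary",
  "required": {
    "seed": "integer",
    "n_sites": "integer",
    "n_individuals": "integer",
    "site_filter": "string",
    "stages": "object"
  },
  "stages": [
    "f3_scan",
    "pca",
    "d_scan",
    "pairwise_f3",
    "qpadm",
    "transversion_replication",
    "downsampling",
    "dating"
  ],
  "stage_status": ["ok", "error"]
}
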