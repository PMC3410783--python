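{
  "type": "object",
  "required": [
    "seed",
    "config",
    "mrna",
    "mirna",
    "integration",
    "enrichment"
  ],
  "properties": {
    "seed": {
      "type": "integer"
    },
    "config": {
      "type": "object",
      "required": [
        "outdir",
        "seed",
        "thresholds"
      ]
    },
    "mrna": {
      "type": "object",
      "required": [
        "n_probes_input",
        "n_probes_after_filter",
        "raw_p_cutoffs",
        "significant",
        "n_significant_union",
        "patterns"
      ],
      "properties": {
        "n_probes_input": {
          "type": "integer"
        },
        "n_probes_after_filter": {
          "type": "integer"
        },
        "raw_p_cutoffs": {
          "type": "object"
        },
        "significant": {
          "type": "object"
        },
        "n_significant_union": {
          "type": "integer"
        },
        "patterns": {
          "type": "object"
        }
      }
    },
    "mirna": {
      "type": "object",
      "required": [
        "n_assays_input",
        "n_detected",
        "raw_p_cutoffs",
        "significant",
        "n_significant_union",
        "patterns"
      ]
    },
    "integration": {
      "type": "object",
      "required": [
        "n_candidate_triples",
        "databases",
        "n_overlap_mrnas"
      ],
      "properties": {
        "n_candidate_triples": {
          "type": "integer"
        },
        "databases": {
          "type": "array"
        },
        "n_overlap_mrnas": {
          "type": "integer"
        }
      }
    },
    "enrichment": {
      "type": "object",
      "required": [
        "top_terms_targeted",
        "comparison_top"
      ],
      "properties": {
        "top_terms_targeted": {
          "type": "array"
        },
        "comparison_top": {
          "type": "array"
        }
      }
    }
  }
}
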