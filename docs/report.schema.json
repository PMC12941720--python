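{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "famburden family report",
  "type": "object",
  "required": ["provenance", "pedigree", "qc", "mendelian_violations"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["tool", "version", "config_sha256", "input_sha256"]
    },
    "pedigree": {
      "type": "object",
      "required": ["family_id", "n_members", "n_blood_relatives", "generations"]
    },
    "qc": {
      "type": "object",
      "required": ["n_panel", "n_in_region", "removed", "n_scored"]
    },
    "mendelian_violations": {"type": "array"},
    "apoe": {"type": "object"},
    "burden": {
      "type": "object",
      "required": [
        "per_individual_total",
        "per_individual_gene_counts",
        "overall",
        "per_generation",
        "gene_means",
        "contribution_percent",
        "sibling_discordance"
      ]
    },
    "methylation": {
      "type": "object",
      "required": ["n_probes_input", "n_probes_kept", "filter_counts", "gene_mean_beta"]
    }
  }
}
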