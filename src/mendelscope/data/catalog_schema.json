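{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mendelscope catalog tables",
  "description": "Column contracts for the packaged skeletal-disorder nosology (nosology.tsv), the studied case series (cases.tsv) and the per-allele variant table (alleles.tsv). All files are UTF-8, tab-delimited, one header row.",
  "definitions": {
    "moi": {"enum": ["AR", "AD", "AcD", "AID", "XLD", "unknown"]},
    "species": {"enum": ["Bos taurus", "Ovis aries"]},
    "classification": {"enum": ["pathogenic", "likely_pathogenic", "uncertain", "none"]},
    "zygosity": {"enum": ["heterozygous", "homozygous", "compound-partner", "hemizygous"]},
    "id_list": {"type": "string", "description": "comma-separated positive integers"}
  },
  "properties": {
    "nosology.tsv": {
      "type": "object",
      "required": ["category", "disorder", "species", "breeds", "gene", "moi", "variant_kinds", "omia_id", "horn_trait"],
      "properties": {
        "category": {"type": "string"},
        "disorder": {"type": "string"},
        "species": {"$ref": "#/definitions/species"},
        "breeds": {"type": "string", "description": "comma-separated"},
        "gene": {"type": "string"},
        "moi": {"$ref": "#/definitions/moi"},
        "variant_kinds": {"type": "string", "description": "comma-separated"},
        "omia_id": {"type": "string"},
        "horn_trait": {"enum": ["0", "1"]},
        "notes": {"type": "string"}
      }
    },
    "cases.tsv": {
      "type": "object",
      "required": ["category", "disorder", "species", "breeds", "gene", "moi", "variant_kinds", "classification", "case_ids"],
      "properties": {
        "category": {"type": "string"},
        "disorder": {"type": "string"},
        "species": {"$ref": "#/definitions/species"},
        "breeds": {"type": "string"},
        "gene": {"type": "string"},
        "moi": {"$ref": "#/definitions/moi"},
        "variant_kinds": {"type": "string"},
        "classification": {"$ref": "#/definitions/classification"},
        "case_ids": {"$ref": "#/definitions/id_list", "description": "unique across the whole table"},
        "notes": {"type": "string"}
      }
    },
    "alleles.tsv": {
      "type": "object",
      "required": ["allele_id", "label", "case_ids", "gene", "hgvs_g", "hgvs_c", "zygosity", "kind", "classification", "codon_consistent"],
      "properties": {
        "allele_id": {"type": "string", "description": "unique; an allele shared by two cases appears once and is referenced twice"},
        "label": {"type": "string"},
        "case_ids": {"$ref": "#/definitions/id_list"},
        "gene": {"type": "string"},
        "hgvs_g": {"type": "string"},
        "hgvs_c": {"type": "string"},
        "hgvs_p": {"type": "string"},
        "zygosity": {"$ref": "#/definitions/zygosity"},
        "kind": {"type": "string"},
        "classification": {"$ref": "#/definitions/classification"},
        "codon_consistent": {"enum": ["0", "1"], "description": "0 flags printed c./p. pairs whose codon arithmetic does not check out"},
        "notes": {"type": "string"}
      }
    }
  }
}
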