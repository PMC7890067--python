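{
  "BRCA1": {
    "n_snps_input": 9072535,
    "n_snps_genotyped": 402336,
    "n_snps_imputed": 8670199,
    "n_excluded_proximal": 2164,
    "n_excluded_control_only": 2070,
    "n_excluded_control_only_same_chrom": 2012,
    "n_excluded_control_only_other_chrom": 58,
    "n_snps_analyzed": 9068301,
    "n_bcac_cases": 60212,
    "n_cimba_cases": 7257,
    "n_bcac_controls": 45881,
    "n_cimba_unaffected": 5750,
    "n_cases_total": 67469,
    "n_bcac_er_negative_cases": 9479,
    "n_er_negative_cases_total": 16736
  },
  "BRCA2": {
    "n_snps_input": 9047403,
    "n_snps_genotyped": 402397,
    "n_snps_imputed": 8645006,
    "n_excluded_proximal": 2947,
    "n_excluded_control_only": 626,
    "n_excluded_control_only_same_chrom": 566,
    "n_excluded_control_only_other_chrom": 60,
    "n_snps_analyzed": 9043830,
    "n_bcac_cases": 57725,
    "n_cimba_cases": 5097,
    "n_bcac_controls": 43549,
    "n_cimba_unaffected": 4456,
    "n_cases_total": 62822
  },
  "lambda_1000_without_pcs": 1.21,
  "lambda_1000_with_4_pcs": 1.03
}
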