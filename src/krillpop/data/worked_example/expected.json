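{
  "comment": "Hand-computed statistics for the 8-chromosome, 5-SNP example. n=8, L_acc=90, pops of 2 diploids each. pi_site = k(8-k)/28 per site: [7/28, 16/28, 16/28, 12/28, 12/28], sum 2.25. Watterson a_7 = 363/140. dxy per site p1(1-p2)+p2(1-p1): [0.25, 1, 0.5, 0.5, 0.5], sum 2.75. WC per-SNP theta-hat worked through the a/b/c components by hand; exon Reynolds over SNPs at POS 20/30/55 gives numerator 0.5 - 1/12 + 1/12 = 0.5, denominator 0.5 + 1/4 + 1/4 = 1.0; genome Reynolds = (7/12)/(11/8) = 14/33.",
  "n_chromosomes": 8,
  "L_acc": 90,
  "S": 5,
  "pi_sum": 2.25,
  "pi_per_base": 0.025,
  "theta_w_per_base": 0.0214263850627487,
  "tajima_d": 0.7563225512360905,
  "dxy_per_base": 0.030555555555555555,
  "wc_fst_per_snp": [0.0, 1.0, 0.0, 0.0, 0.0],
  "exon_reynolds_fst": 0.5,
  "genome_reynolds_fst": 0.42424242424242425
}
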