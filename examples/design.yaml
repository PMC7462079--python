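# Six-gene mixed-strand fixture: coupled pairs (theta 6 and 0.25),
# an intronic site, an acceptor-AG site, a planted SNP, and a null site.
coverage: 60
n_random_snps: 3
genes:
- name: geneA
  strand: +
  exon_lengths:
  - 150
  - 150
  intron_lengths:
  - 120
- name: geneB
  strand: '-'
  exon_lengths:
  - 150
  - 150
  intron_lengths:
  - 120
- name: geneC
  strand: +
  exon_lengths:
  - 150
  - 150
  - 150
  intron_lengths:
  - 120
  - 120
- name: geneD
  strand: '-'
  exon_lengths:
  - 150
  - 150
  intron_lengths:
  - 120
- name: geneE
  strand: +
  exon_lengths:
  - 150
  - 150
  intron_lengths:
  - 120
- name: geneF
  strand: +
  exon_lengths:
  - 150
  - 150
  intron_lengths:
  - 120
sites:
- name: siteA
  gene: geneA
  intron_index: 0
  side: donor
  offset: 2
  eps_wt: 0.6
  eps_ko: 0.05
  psi_wt: 0.8399999999999999
  psi_ko: 0.7116666666666666
  theta: 6.0
  is_snp: false
- name: siteB
  gene: geneB
  intron_index: 0
  side: donor
  offset: 2
  eps_wt: 0.6
  eps_ko: 0.05
  psi_wt: 0.5010526315789473
  psi_ko: 0.6834210526315788
  theta: 0.25
  is_snp: false
- name: siteC
  gene: geneC
  intron_index: 1
  side: acceptor
  offset: -5
  eps_wt: 0.3
  eps_ko: 0.3
  psi_wt: 0.6
  psi_ko: 0.6
  theta: 1.0
  is_snp: false
- name: siteD
  gene: geneD
  intron_index: 0
  side: acceptor
  offset: 1
  eps_wt: 0.4
  eps_ko: 0.0
  psi_wt: 0.7
  psi_ko: 0.7
  theta: 1.0
  is_snp: false
- name: siteE
  gene: geneE
  intron_index: 0
  side: donor
  offset: 10
  eps_wt: 0.5
  eps_ko: 0.5
  psi_wt: 0.8
  psi_ko: 0.8
  theta: 1.0
  is_snp: true
- name: siteF
  gene: geneF
  intron_index: 0
  side: donor
  offset: -20
  eps_wt: 0.2
  eps_ko: 0.2
  psi_wt: 0.5
  psi_ko: 0.5
  theta: 1.0
  is_snp: false
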