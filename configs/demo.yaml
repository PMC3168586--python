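# Desk-scale demonstration of the full simulate -> call -> filter -> burden
# workflow: ~3,000 probes on a 3 x 10-Mbp genome, 10 cases + 15 controls.
# CNVs given by size_bp are placed inside hotspot regions of the generated
# design (the array's densely tiled rearrangement-prone regions).
seed: 7
outdir: demo_out
design:
  chrom_sizes: {chr1: 10000000, chr2: 10000000, chr3: 10000000}
  n_hotspots: 8
  n_probes_target: 3000
  hotspot_spacing_bp: 2600
  backbone_spacing_bp: 36000
cohort:
  n_cases: 10
  n_controls: 15
noise:
  probe_noise_sd: 0.15
  sample_baseline_sd: 0.05
cnvs:
  # a large (>500 kbp) deletion enriched in cases
  - {size_bp: 600000, kind: deletion, frequency: 0.4, group: case, locus: L1}
  - {size_bp: 600000, kind: deletion, frequency: 0.1, group: control, locus: L1}
  # a common (non-rare) duplication carried by both groups
  - {size_bp: 150000, kind: duplication, frequency: 0.5, group: both}
  # a rare case-only deletion
  - {size_bp: 450000, kind: deletion, frequency: 0.2, group: case}
burden_min_size_bp: 500000
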