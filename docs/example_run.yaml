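# Example pipeline configuration (paths relative to this file).
# CLI flags override file values:  famburden report --config run.yaml --out report.json
pedigree: ../data/pedigree.ped
vcf: ../data/genotypes.vcf
panel: ../data/panel.tsv
regions: ../data/regions.tsv
beta: ../data/beta.tsv
manifest: ../data/manifest.tsv
detection_p: ../data/detection_p.tsv
flank_bp_variants: 50000
flank_bp_probes: 10000
detp_threshold: 0.01
burden_decimals: 1
correlation_decimals: 3
seed: 0
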