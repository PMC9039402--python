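# Demo configuration: full pipeline on the default synthetic study.
# All thresholds default to the analysis' standard values
# (fc=2, p=0.05, pcc=0.9, fimo_p=1e-4, hub_fraction=0.2, n_null=1000, flank=2000).
#
#   cernet run-all --config configs/demo.yaml --seed 7 --out results/demo

synthdata: {}          # SynthConfig defaults: 89 tumor / 3 normal samples,
                       # 150 miRNAs, 100 lncRNAs, 300 mRNAs, 30% DE at |log2FC|=2.5

thresholds:
  n_null: 1000
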