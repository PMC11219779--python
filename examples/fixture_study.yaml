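# Desk-scale study on the bundled reduced apoptosis model.
# Run with:  boedpd run --config examples/fixture_study.yaml --out results/ --seed 1
# Campaign-scale settings (n_replicates: 100, chain_length: 50000) are accepted
# by the same schema.
designs: [Casp_act, Casp_pro, mRNA_Bax, Bad_Bcl_xL, p53_act]
u_grid: [0.001, 0.01, 0.032, 0.1, 0.32, 1.0, 3.2, 10.0, 100.0]
thresholds: [0.5, 0.6, 0.7, 0.8, 0.9]
u_star: 0.01
t_star: 0.9
w1_list: [0.01, 0.1]
n_replicates: 10
chain_length: 2000
warmup_frac: 0.2
target_accept: 0.8
rel_err: 0.10
u_nominal: 1.0
n_sub: 200
apply_bounds: true
constraint_filtering: true
seed: 1
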