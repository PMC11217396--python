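# End-state waist statistics as a function of goal-matrix rank,
# at small initial link intensity. Desk scale; use --full for 100
# replicates per condition.
experiment = "waist_vs_rank"
replicates = 20
ranks = [1, 2, 3, 4, 5, 6]
A0_values = [0.01]
M = 6
L = 4
norm = 60.0
seed = 1

[config]
N = 100
max_generations = 60000
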