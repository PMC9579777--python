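# Full-scale asexual run at the intermediate cost exponent: disruptive
# selection at the interior singular point splits the ability distribution.
p = 1.5
mode = "asexual"
n_individuals = 1000
n_generations = 10001
initial_ability = 1.0
mutation_prob = 0.01
mutation_sd = 0.05
record_every = 10
seed = 42
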