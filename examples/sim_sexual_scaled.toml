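# Reduced-scale sexual run (infinitesimal-model inheritance), quick to
# execute; selection pushes ability down when the cost exponent is 1.25.
p = 1.25
mode = "sexual"
n_individuals = 500
n_generations = 2000
initial_ability = 1.0
segregation_sd = 0.05
record_every = 20
seed = 1
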