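"""Estimate trophic positions from trophic/source amino acid d15N pairs.

Builds a two-sample toy dataset and applies both shipped
parameterizations. TP = ((d15N_trophic - d15N_source) - beta)/TDF + 1:
a herbivorous consumer one step above the producer baseline has TP = 2.
"""

from aacsia import (ALA_PHE, GLX_PHE, Dataset, SampleRecord, batch_tp)

herbivore = SampleRecord(sample_id="herbivore")
herbivore.set("Phe", "d15N", 3.4, sd=0.42, n_reps=3)
herbivore.set("Glx", "d15N", 14.4, sd=0.42, n_reps=3)   # 3.4 + beta + TDF
herbivore.set("Ala", "d15N", 11.1, sd=0.42, n_reps=3)

carnivore = SampleRecord(sample_id="carnivore")
carnivore.set("Phe", "d15N", 3.4, sd=0.42, n_reps=3)
carnivore.set("Glx", "d15N", 22.0, sd=0.42, n_reps=3)   # one more TDF step
carnivore.set("Ala", "d15N", 15.6, sd=0.42, n_reps=3)

dataset = Dataset(records=[herbivore, carnivore])
for params in (GLX_PHE, ALA_PHE):
    estimates, _ = batch_tp(dataset, params)
    for e in estimates:
        print(f"{e.sample_id:10s} TP({params.name}) = {e.tp:.2f} "
              f"+/- {e.tp_sd:.3f}")

# The +/- value is the replicate-noise SD propagated through the
# estimator (sqrt(sd_t^2 + sd_s^2)/TDF); beta and TDF are fixed.
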