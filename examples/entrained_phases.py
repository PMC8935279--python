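"""Entrained peak phases (ZT) of the four clock genes under 12:12 LD.

ZT (Zeitgeber Time) is hours after dawn; a negative value means the peak
falls shortly before dawn.  The canonical ordering -- CL at dawn, P97
mid-morning, EL early evening, P51 at dusk -- is the wave of expression that
structures the plant's day.
"""

from plantclock.fitting import FitSpec, observables
from plantclock.parameters import DEFAULT_PARAMS

obs = observables(DEFAULT_PARAMS, FitSpec())

print("entrained:", bool(obs["entrained"][0]))
for gene, label in [("CL", "CCA1/LHY"), ("P97", "PRR9/PRR7"),
                    ("P51", "PRR5/TOC1"), ("EL", "ELF4/LUX")]:
    print(f"  {label:10s} mRNA peak at ZT {float(obs[f'ZT_{gene}'][0]):+5.1f} h")
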