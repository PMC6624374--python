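"""Analytic attenuation of vitamin B1 along the food chain.

With a bioavailability b per feeding transfer, a pool of B1 entering
the chain survives b**n after n consumer levels.  From picoalgae the
route to planktivorous fish crosses four levels (nanoflagellates,
ciliates, mesozooplankton, fish); from microalgae only two — which is
why large primary producers matter so much for B1 supply to fish.
"""

from b1web import decay_chain
from b1web.metrics import CONSUMER_LEVELS_TO_FISH

for b in (0.15, 0.10):
    print(f"bioavailability b = {b:.2f}")
    for entry, n in CONSUMER_LEVELS_TO_FISH.items():
        r = decay_chain(b, n)
        print(f"  {entry:12s} -> fish: {n} levels, "
              f"{r.surviving_fraction * 100:8.4f}% survives "
              f"({r.fold_reduction:8.1f}-fold reduction)")
    print()

print("Reading: at b = 0.15 only ~0.5 permille of B1 made by picoalgae "
      "can reach fish (~2000-fold loss), versus ~2% from microalgae; "
      "dropping b to 0.10 turns the picoalgae route into a ~10000-fold loss.")
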