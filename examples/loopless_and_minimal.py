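"""Thermodynamic loop removal and random minimal networks.

The loop fixture adds a futile internal cycle (A -> B, B -> A) beside a
working pathway: plain FBA may circulate arbitrary flux through the
cycle without changing growth, while loop removal (tfba) forbids any
internal cycle not driven through an exchange.  The branched fixture has
two redundant routes; a random minimal network keeps exactly one of
them, chosen by the seed.
"""

from gemkit import fba, make_fixture, randomsparse

loop = make_fixture("loop")
loopless = fba(loop, loop_removal="tfba")
print(f"Loopless growth: {loopless.objective_value:g}")
print(f"  cycle fluxes: R_AB2={loopless.fluxes['R_AB2']:g}, "
      f"R_BA={loopless.fluxes['R_BA']:g}  (forced to zero)")

branched = make_fixture("branched")
for seed in (0, 1):
    network = randomsparse(branched, mode="reactions", seed=seed)
    kept = sorted(network.retained & {"P1a", "P1b", "P2a", "P2b"})
    print(f"seed {seed}: retained route {kept}, "
          f"deleted {sorted(network.deleted)}")
# Every retained reaction is essential: deleting any one of them drops
# growth below the threshold.
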