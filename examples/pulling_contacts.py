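"""Steered pull-out with force-adjusted contact statistics.

Pulls a ligand coordinate through the substrate (downhill) and the
non-substrate (entry-barrier) landscape archetypes, records per-residue
zone contacts, and prints how contact localisation differs: substrates
accumulate contacts at the extracellular-gate zones, non-substrates at
the entry/inner-leaflet zones where translocation stalls.
"""

import numpy as np

import gatekeeper as gk
from gatekeeper.synth import COUNTERACT_RESIDUES, PROMOTE_RESIDUES, ZONE_CENTERS

zones = [gk.ResidueZone(r, c) for r, c in ZONE_CENTERS.items()]
pull = gk.PullConfig(force_constant=1.0, velocity=40.0)  # desk-rescaled

for name, archetype in (("substrate", "substrate_downhill"),
                        ("non-substrate", "nonsubstrate_entry_barrier")):
    land = gk.make_landscape(archetype)
    tables = []
    for rep in range(10):
        traj = gk.run_constant_velocity_pull(
            land, pull, walls=gk.WallSpec(), zones=zones, z_start=-1.0,
            n_steps=60_000, seed=100 + rep)
        tables.append(gk.adjusted_contact_frequencies(traj, window=10.0))
    mean = gk.mean_table(tables).table.set_index("residue")
    gate = mean.loc[list(PROMOTE_RESIDUES)].raw_frequency.mean()
    entry = mean.loc[list(COUNTERACT_RESIDUES)].raw_frequency.mean()
    print(f"{name:14s} gate-zone contact {gate:.3f}   entry-zone contact {entry:.3f}")
# Higher gate-zone contact for the substrate and higher entry-zone contact
# for the non-substrate mirror the contact maps that distinguish
# transported from rejected molecules.
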