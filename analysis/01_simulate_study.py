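"""Simulate the reference colonization study used by the downstream analyses.

Generates an 11-species hierarchical ground truth and a full study —
monocultures (8 replicates), all 55 pairs (4), all 20 trios of the first six
species (4), one 8-species community (3) — in the worm gut (host AU37) and,
for the environment comparison, in liquid media with a handful of pairs
shifted toward exclusion.  A second, immunocompetent host strain (SS104) is
simulated with uneven carrying-capacity suppression.  Tables land in
results/study/.
"""

import itertools
from pathlib import Path

from gutassembly import make_ground_truth, simulate_study, write_cfu_table

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "study"
OUT.mkdir(parents=True, exist_ok=True)

gt = make_ground_truth(11, mode="hierarchical", seed=SEED)

# media fractions: mostly the worm values, but push a few coexisting pairs to
# exclusion (the gut permits more coexistence than the feeding substrate)
Fm = gt.F_true.copy()
shifted = []
for i, j in itertools.combinations(gt.species_ids, 2):
    if 0.25 < Fm.loc[i, j] < 0.45 and len(shifted) < 4:
        Fm.loc[i, j], Fm.loc[j, i] = 0.005, 0.995
        shifted.append((i, j))
gt.F_media = Fm

# immunocompetent host: ~4x lower loads on average, uneven across species
suppression = {
    sp: 0.25 * (0.2 if k % 4 == 0 else 1.6 if k % 4 == 1 else 1.0)
    for k, sp in enumerate(gt.species_ids)
}

study = simulate_study(
    gt,
    design={
        "environments": ["worm", "media"],
        "host_strains": ["AU37", "SS104"],
        "host_k_scale": {"SS104": suppression},
    },
    seed=SEED,
)

write_cfu_table(study.cfu_table, OUT / "cfu_table.csv")
gt.save(OUT / "ground_truth.yaml")

n_cond = len(study.cfu_table.conditions())
print(f"simulated {n_cond} conditions ({len(study.cfu_table)} rows)")
print(f"media pairs shifted to exclusion: {['-'.join(p) for p in shifted]}")
print(f"tables in {OUT}")
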