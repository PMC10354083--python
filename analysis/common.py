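"""Shared configuration for the analysis scripts.

One demonstration world is used across the numbered drivers: a 70x70 km
landscape with four cities, 8,000 checklists whose placement is biased
toward bright pixels, and 12 species whose true radiance slopes follow a
known body-mass relationship (slope -0.25 per SD of mass on the index
scale, noise SD 0.05).  Sizes are chosen so the whole sequence runs in a
couple of minutes on a laptop.
"""

from pathlib import Path

import urbantol as ut

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
WORLD_DIR = RESULTS / "world"

SEED = 7
N_SPECIES = 12
MASS_EFFECT = -0.25
NOISE_SD = 0.05
N_RUNS = 10
MIN_DETECTIONS = 200


def world_config() -> ut.SyntheticConfig:
    return ut.SyntheticConfig(
        extent_km=(70.0, 70.0),
        n_cities=4,
        n_checklists=8000,
        violations=ut.ViolationFractions(
            incomplete=0.02, protocol=0.02, duration=0.02, distance=0.02, date=0.02
        ),
        seed=SEED,
    )


def species_truths():
    traits, true_index = ut.simulate_trait_table(
        N_SPECIES, mass_effect=MASS_EFFECT, noise_sd=NOISE_SD, seed=SEED, intercept=0.0
    )
    truths = [
        ut.SpeciesTruth(code, beta0=-0.3, beta_alan=float(b), theta=2.0)
        for code, b in true_index.items()
    ]
    return traits, true_index, truths
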