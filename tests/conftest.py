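import numpy as np
import pytest

from clocklight import chip as chip_mod
from clocklight import synth
from clocklight.light import CONDITIONS, make_light_profile
from clocklight.regulators import make_regulator_trajectories


@pytest.fixture(scope="session")
def light_profiles():
    return {c: make_light_profile(c) for c in CONDITIONS}


@pytest.fixture(scope="session")
def regulator_trajectories(light_profiles):
    return {c: make_regulator_trajectories(lp) for c, lp in light_profiles.items()}


@pytest.fixture(scope="session")
def noiseless_study():
    """Dusk-cluster dataset with no observation noise (seed 1)."""
    return synth.make_dusk_dataset(synth.SyntheticScenario(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def gene_counts_dataset():
    """Planted-cosinor count matrix at the default study noise level."""
    counts, lengths, annotation, truth, scale = synth.make_gene_counts(
        n_genes=300, seed=7, noise_sd=0.05
    )
    return {
        "counts": counts,
        "lengths": lengths,
        "annotation": annotation,
        "truth": truth,
        "scale": scale,
    }


@pytest.fixture(scope="session")
def chip_fixture():
    """Two-replicate IP/mock tracks with planted summits on a 200 kb genome."""
    genome = 200_000
    planted = [
        (20_000, 5.0, 200.0),
        (60_000, 4.0, 200.0),
        (100_000, 3.4, 200.0),
        (140_000, 6.0, 150.0),
    ]
    replicates = synth.make_chip_tracks(genome, planted, seed=2)
    smoothed = [
        (chip_mod.smooth_track(ip), chip_mod.smooth_track(mock)) for ip, mock in replicates
    ]
    return {"genome": genome, "planted": planted, "raw": replicates, "smoothed": smoothed}
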