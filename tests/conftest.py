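import numpy as np
import pandas as pd
import pytest

from cookin import features, synth
from cookin.pedigree import Pedigree


@pytest.fixture(scope="session")
def small_scenario():
    """A 12-female paper_like colony small enough for fast module tests."""
    pop, ac = synth.scenario_config(
        "paper_like", seed=11,
        pop_n_females=12, pop_n_matrilines=3, pop_n_groups=2,
        pop_calls_per_female_range=(4, 6),
    )
    return pop, ac


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    pop, ac = small_scenario
    return synth.simulate_dataset(pop, ac)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return features.extract_table(small_dataset.calls)


def make_pedigree(rows):
    """Pedigree from (id, dam, sire) triples; metadata defaulted."""
    df = pd.DataFrame(rows, columns=["id", "dam_id", "sire_id"])
    df["sex"] = "F"
    df["birth_year"] = 2000
    df["group"] = "G0"
    df["matriline"] = "M0"
    return Pedigree(df)


@pytest.fixture
def tone():
    def _tone(freq: float, duration: float = 1.0, sr: int = 44100, amp: float = 0.5):
        t = np.arange(int(duration * sr)) / sr
        return synth.CallRecording(
            call_id=f"tone{freq}", female_id="t", sample_rate=sr,
            waveform=amp * np.sin(2 * np.pi * freq * t),
        )
    return _tone


def simulate_dyadic_data(
    seed: int,
    n_members: int = 30,
    n_dyads: int = 200,
    beta: dict | None = None,
    sd_member: float = 0.3,
    sd_res: float = 0.3,
) -> pd.DataFrame:
    """Dyadic LMM data straight from the model's own generative process.

    Members get random intercepts for the A and B slots; covariates mimic
    the study design (zero-inflated relatedness, three-level gm factor,
    continuous age difference).  ``beta`` maps design columns to fixed
    effects; the intercept is 1.5.
    """
    from cookin.lmm import dyad_design

    rng = np.random.default_rng(seed)
    pairs = np.array([(i, j) for i in range(n_members) for j in range(i + 1, n_members)])
    take = rng.choice(len(pairs), size=min(n_dyads, len(pairs)), replace=False)
    pairs = pairs[np.sort(take)]
    n = len(pairs)

    r = np.where(rng.random(n) < 0.7, 0.0,
                 rng.choice([0.0625, 0.125, 0.25, 0.5], size=n))
    gm = rng.choice(
        ["same_group_same_matriline", "same_group_diff_matriline",
         "diff_group_diff_matriline"], size=n, p=[0.3, 0.2, 0.5])
    aged = rng.uniform(0, 20, size=n)

    df = pd.DataFrame({
        "id_a": [f"F{i:03d}" for i in pairs[:, 0]],
        "id_b": [f"F{j:03d}" for j in pairs[:, 1]],
        "r": r,
        "gm_level": gm,
        "age_diff": aged,
        "kin_class": np.where(r > 0, "kin", "nonkin"),
    })
    df["rel_z"] = (r - r.mean()) / r.std()
    sq = np.sqrt(aged)
    df["aged_z"] = (sq - sq.mean()) / sq.std()
    df = dyad_design(df)

    u_a = rng.normal(0, sd_member, n_members)
    u_b = rng.normal(0, sd_member, n_members)
    y = 1.5 + u_a[pairs[:, 0]] + u_b[pairs[:, 1]] + rng.normal(0, sd_res, n)
    for col, b in (beta or {}).items():
        y = y + b * df[col].to_numpy()
    df["y"] = y
    return df
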