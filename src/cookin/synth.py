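"""Synthetic coo-call populations with known kin / familiarity structure.

This module generates everything the downstream pipeline consumes when no
field recordings are available: a three-generation pedigree of focal adult
females organised into groups and matrilines, a heritable latent acoustic
trait transmitted under the additive infinitesimal model, and per-call
harmonic waveforms whose fundamental frequency carries four separable
effects:

* an *individual signature* (idiosyncratic per-female offset),
* a *heritable* component proportional to the latent trait, so that kin
  resemble each other in proportion to their relatedness,
* a *familiarity* component implemented as convergence of each female's
  signature toward a group-level and matriline-level "vocal tradition"
  offset (vocal accommodation), and
* a linear *age trend*.

Calls are arched tonal sounds: a raised-cosine F0 contour with a harmonic
stack under geometric (dB-per-harmonic) amplitude decay, plus white noise
at a configurable SNR — a deliberately minimal emulation of a macaque coo.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .pedigree import Pedigree

__all__ = [
    "PopulationConfig",
    "AcousticEffectConfig",
    "CallRecording",
    "SimulatedDataset",
    "generate_population",
    "assign_latent_traits",
    "female_profiles",
    "synthesize_call",
    "simulate_dataset",
    "write_dataset",
    "scenario_config",
    "InvalidConfigError",
    "DegenerateCallError",
]

REFERENCE_YEAR = 2010  # "today" for age computation
N_LATENT_CHANNELS = 4   # one heritable channel per signature parameter


class InvalidConfigError(ValueError):
    pass


class DegenerateCallError(ValueError):
    pass


@dataclass
class PopulationConfig:
    """Demography of the simulated colony.

    ``sire_skew`` concentrates paternity: 0 spreads focal offspring evenly
    over the sire pool (maximal paternal diversity), 1 assigns every
    offspring to a single dominant male.  Intermediate values sample sires
    with geometrically decaying weights, so paternal half-sib dyads occur
    both within and across groups.
    """

    n_females: int = 67
    n_groups: int = 4
    n_matrilines: int = 7
    age_range: tuple[float, float] = (4, 24)
    calls_per_female_range: tuple[int, int] = (4, 14)
    founder_generations: int = 2
    sire_skew: float = 0.15
    n_sires: int | None = None
    cross_group_matrilines: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_females < 2:
            raise InvalidConfigError("need at least 2 focal females")
        if self.n_matrilines > self.n_females:
            raise InvalidConfigError("more matrilines than females")
        if self.n_groups > self.n_matrilines:
            raise InvalidConfigError("more groups than matrilines")
        if not (0.0 <= self.sire_skew <= 1.0):
            raise InvalidConfigError("sire_skew must lie in [0, 1]")
        lo, hi = self.calls_per_female_range
        if not (1 <= lo <= hi <= 50):
            raise InvalidConfigError("calls_per_female_range must lie within [1, 50]")
        if self.founder_generations < 2:
            raise InvalidConfigError("need at least two ancestral generations")


@dataclass
class AcousticEffectConfig:
    """Acoustic parameters and effect weights of the call generator.

    Units: Hz for frequencies, seconds for durations, dB for tilt and SNR.
    ``h2_weight`` blends the heritable latent trait into every signature
    parameter (1.0 means heritable and idiosyncratic parts weigh equally;
    kin signatures correlate at h2_weight^2 r / (1 + h2_weight^2));
    ``fam_weight`` in [0, 1] is the pull of each signature toward the
    group/matriline vocal tradition; ``age_slope`` is Hz per year.
    """

    base_f0: float = 520.0
    sd_individual: float = 30.0
    h2_weight: float = 0.0
    fam_weight: float = 0.0
    age_slope: float = 0.0
    duration_mean: float = 0.45
    duration_cv: float = 0.12
    n_harmonics: int = 6
    spectral_tilt_db: float = -6.0
    snr_db: float = 30.0
    arch_depth: float = 0.18
    jitter_cv: float = 0.03
    arch_jitter_cv: float = 0.12
    tilt_jitter_db: float = 0.8
    sample_rate: int = 44100
    seed: int = 0

    def validate(self) -> None:
        if self.n_harmonics < 3:
            raise InvalidConfigError("need >= 3 harmonics (F0-to-3rd-harmonic ratio)")
        if not np.isfinite(self.snr_db):
            raise InvalidConfigError("snr_db must be finite")
        for name in ("sd_individual", "duration_mean", "duration_cv", "jitter_cv"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.fam_weight <= 1.0):
            raise InvalidConfigError("fam_weight must lie in [0, 1]")


@dataclass
class CallRecording:
    """One mono call waveform plus caller metadata."""

    call_id: str
    female_id: str
    sample_rate: int
    waveform: np.ndarray
    group: str = ""
    matriline: str = ""
    birth_year: int = 0
    age_years: float = 0.0

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sample_rate


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    membership: pd.DataFrame  # one row per focal female
    calls: list[CallRecording]
    truth: dict


# ---------------------------------------------------------------------------
# population / pedigree
# ---------------------------------------------------------------------------


def _skewed_assign(rng: np.random.Generator, n_draws: int, pool: list[str], skew: float) -> list[str]:
    """Assign sires to offspring.

    skew = 0 cycles through a shuffled pool (even paternity, no collisions
    while the pool lasts); skew = 1 gives all offspring to pool[0]; in
    between, weights decay geometrically with rank.
    """
    if skew >= 1.0:
        return [pool[0]] * n_draws
    if skew <= 0.0:
        order = list(rng.permutation(pool))
        reps = int(np.ceil(n_draws / len(order)))
        return (order * reps)[:n_draws]
    w = (1.0 - skew) ** np.arange(len(pool))
    w /= w.sum()
    idx = rng.choice(len(pool), size=n_draws, p=w)
    return [pool[i] for i in idx]


def generate_population(cfg: PopulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Build a three-generation pedigree and the focal membership table.

    Returns the pedigree (founders with unknown parents, then a parental
    generation, then the focal females — each focal female has an
    identified dam, sire and four grandparents) and a membership DataFrame
    with one row per focal female: id, group, matriline, birth_year,
    age_years, n_calls.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # distribute focal females over matrilines (each matriline non-empty)
    sizes = np.full(cfg.n_matrilines, 1)
    extra = rng.multinomial(cfg.n_females - cfg.n_matrilines, np.ones(cfg.n_matrilines) / cfg.n_matrilines)
    sizes = sizes + extra
    matriline_of_focal: list[int] = []
    for m, k in enumerate(sizes):
        matriline_of_focal += [m] * int(k)

    # matrilines nested in groups round-robin
    group_of_matriline = {m: m % cfg.n_groups for m in range(cfg.n_matrilines)}

    rows: list[dict] = []

    def add(ind: str, dam: str = "", sire: str = "", sex: str = "F", by: int = 0,
            group: str = "", matriline: str = "") -> None:
        rows.append(dict(id=ind, dam_id=dam, sire_id=sire, sex=sex,
                         birth_year=by, group=group, matriline=matriline))

    # gen-1 (parental) sire pool, with gen-0 parents
    n_sires1 = cfg.n_sires if cfg.n_sires is not None else max(2, cfg.n_females // 3)
    n_gsires = max(2, 2 * n_sires1)
    for j in range(n_gsires):
        add(f"GS{j}", sex="M", by=REFERENCE_YEAR - 40)
    gsire_pool = [f"GS{j}" for j in range(n_gsires)]
    # at zero skew the grandsire pool is partitioned between sires' fathers
    # and founder-dam mates so no grandsire is shared across lineages
    sire_father_pool = gsire_pool[:n_sires1] if cfg.sire_skew == 0 else gsire_pool
    sire_gsires = _skewed_assign(rng, n_sires1, sire_father_pool, 0.0)
    sire_pool = []
    for j in range(n_sires1):
        gd = f"GD{j}"  # each gen-1 sire gets his own founder dam
        add(gd, sex="F", by=REFERENCE_YEAR - 40)
        sid = f"S{j}"
        add(sid, dam=gd, sire=sire_gsires[j], sex="M", by=REFERENCE_YEAR - 25)
        sire_pool.append(sid)

    # paternity assigned globally (not per matriline) so that zero skew
    # really yields distinct sires and grandsires across the whole colony
    sizes_by_mat = {m: int(k) for m, k in enumerate(sizes)}
    dams1_by_mat = {m: max(1, int(np.ceil(0.7 * k))) for m, k in sizes_by_mat.items()}
    dams0_by_mat = {m: max(1, int(np.ceil(dams1_by_mat[m] / 3))) for m in sizes_by_mat}
    n_mates = sum(dams0_by_mat.values())
    if cfg.sire_skew == 0:
        # distinct mates from the half of the pool not used by sires' fathers
        all_mates = _skewed_assign(rng, n_mates, gsire_pool[n_sires1:], 0.0)
    else:
        # founder-generation paternity is uniform: dominance turned over
        # across the decades separating the founder cohorts
        all_mates = [gsire_pool[int(i)]
                     for i in rng.integers(0, len(gsire_pool), n_mates)]
    mate_cursor = 0
    all_focal_sires = _skewed_assign(rng, cfg.n_females, sire_pool, cfg.sire_skew)
    sire_cursor = 0

    membership_rows = []
    focal_counter = 0
    for m in range(cfg.n_matrilines):
        k = sizes_by_mat[m]
        mat = f"M{m}"
        # founder (grandmaternal) females of the matriline
        n_dams1 = dams1_by_mat[m]
        n_dams0 = dams0_by_mat[m]
        for a in range(n_dams0):
            add(f"{mat}F{a}", sex="F", by=REFERENCE_YEAR - 40, matriline=mat)
        # parental-generation dams: dam = matriline founder; founder dams
        # keep a primary mate, so parental sisters are usually full sibs
        dam0_of_dam1 = _skewed_assign(rng, n_dams1, [f"{mat}F{a}" for a in range(n_dams0)], 0.0)
        mate_of_dam0 = {f"{mat}F{a}": all_mates[mate_cursor + a] for a in range(n_dams0)}
        mate_cursor += n_dams0
        for b in range(n_dams1):
            if cfg.sire_skew > 0 and rng.random() >= 0.8:
                gs = gsire_pool[int(rng.integers(len(gsire_pool)))]
            else:
                gs = mate_of_dam0[dam0_of_dam1[b]]
            add(f"{mat}D{b}", dam=dam0_of_dam1[b], sire=gs,
                sex="F", by=REFERENCE_YEAR - 25, matriline=mat)
        # focal females; maternal sibs reuse their elder sib's sire with
        # probability 1/2 (mate fidelity across seasons -> full sibs exist)
        dams_for_focal = _skewed_assign(rng, k, [f"{mat}D{b}" for b in range(n_dams1)], 0.0)
        sires_for_focal = all_focal_sires[sire_cursor : sire_cursor + k]
        sire_cursor += k
        sire_of_dam: dict[str, str] = {}
        for idx in range(k):
            dam = dams_for_focal[idx]
            if dam in sire_of_dam and cfg.sire_skew > 0 and rng.random() < 0.5:
                sires_for_focal[idx] = sire_of_dam[dam]
            else:
                sire_of_dam[dam] = sires_for_focal[idx]
        base_group = group_of_matriline[m]
        for idx, (dam, sire) in enumerate(zip(dams_for_focal, sires_for_focal)):
            fid = f"F{focal_counter:03d}"
            focal_counter += 1
            group = base_group
            if m < cfg.cross_group_matrilines and idx % 2 == 1:
                group = (base_group + 1) % cfg.n_groups  # fissioned half of the matriline
            age = int(rng.integers(int(cfg.age_range[0]), int(cfg.age_range[1]) + 1))
            by = REFERENCE_YEAR - age
            add(fid, dam=dam, sire=sire, sex="F", by=by, group=f"G{group}", matriline=mat)
            lo, hi = cfg.calls_per_female_range
            membership_rows.append(dict(
                id=fid, group=f"G{group}", matriline=mat, birth_year=by,
                age_years=float(age), n_calls=int(rng.integers(lo, hi + 1)),
            ))

    ped = Pedigree(pd.DataFrame(rows))
    membership = pd.DataFrame(membership_rows)
    return ped, membership


def assign_latent_traits(ped: Pedigree, cfg: AcousticEffectConfig) -> pd.DataFrame:
    """Latent acoustic genotypes for every pedigree member.

    Four independent heritable channels (g, g2, g3, g4), one per signature
    parameter — distinct acoustic parameters rest on distinct anatomical
    and neural substrates, so their genetic bases segregate independently.
    Founders draw each channel ~ N(0, 1); every non-founder receives the
    midparent value plus segregation noise of variance 1/2 (additive
    infinitesimal model), so the latent-trait correlation of relatives
    scales with their relatedness, channel by channel.  Individuals with
    exactly one known parent are a pedigree integrity error.
    """
    rng = np.random.default_rng([cfg.seed, 0xA11E1E])
    k = N_LATENT_CHANNELS
    g: dict[str, np.ndarray] = {}
    remaining = list(ped.table["id"])
    while remaining:
        progressed = False
        deferred = []
        for ind in remaining:
            dam, sire = ped.parents(ind)
            if dam == "" and sire == "":
                g[ind] = rng.normal(0.0, 1.0, size=k)
                progressed = True
            elif dam != "" and sire != "":
                if dam in g and sire in g:
                    g[ind] = 0.5 * (g[dam] + g[sire]) + rng.normal(0.0, np.sqrt(0.5), size=k)
                    progressed = True
                else:
                    deferred.append(ind)
            else:
                raise InvalidConfigError(
                    f"{ind!r} has exactly one known parent; latent traits need both or neither"
                )
        remaining = deferred
        if remaining and not progressed:
            raise InvalidConfigError("unresolvable parent references in pedigree")
    out = pd.DataFrame({"individual_id": list(g)})
    mat = np.vstack(list(g.values()))
    for j in range(k):
        out["g" if j == 0 else f"g{j + 1}"] = mat[:, j]
    return out


# ---------------------------------------------------------------------------
# acoustic profiles and waveforms
# ---------------------------------------------------------------------------


def female_profiles(
    membership: pd.DataFrame,
    latents: pd.DataFrame,
    cfg: AcousticEffectConfig,
) -> pd.DataFrame:
    """Per-female acoustic parameters implied by the effect configuration.

    Each of the four signature parameters (F0 offset, log duration, arch
    depth, spectral tilt) is built from ``(z + h2_weight * g) / sqrt(1 +
    h2_weight**2)`` — an idiosyncratic normal deviate blended with the
    heritable latent trait at constant total variance, so kin signatures
    correlate at ``h2_weight**2 r / (1 + h2_weight**2)``.  Familiarity then
    pulls every signature toward a group-level plus matriline-within-group
    "vocal tradition" offset with weight ``fam_weight``, making dyads of
    the same group (and more so the same matriline) more similar.  F0
    finally adds the linear age trend around the sample mean age.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0xF0])
    mem = membership.sort_values("id").reset_index(drop=True)
    n = len(mem)
    lat = latents.set_index("individual_id")
    gmat = lat.loc[mem["id"], ["g", "g2", "g3", "g4"]].to_numpy()
    gvec = gmat[:, 0]

    z_f0 = rng.normal(size=n)
    z_dur = rng.normal(size=n)
    z_arch = rng.normal(size=n)
    z_tilt = rng.normal(size=n)

    # each signature parameter blends its own heritable channel with an
    # idiosyncratic deviate; normalized so signature variance is
    # independent of h2_weight and kin correlation is h2^2 r / (1 + h2^2)
    h2 = cfg.h2_weight
    norm = np.sqrt(1.0 + h2**2)

    def signature(z: np.ndarray, channel: int) -> np.ndarray:
        return (z + h2 * gmat[:, channel]) / norm

    # vocal accommodation: each signature is pulled toward a group-level and
    # a matriline-within-group "vocal tradition" offset of unit scale
    groups = sorted(mem["group"].unique())
    gmats = sorted(set(zip(mem["group"], mem["matriline"])))

    def converge(values: np.ndarray) -> np.ndarray:
        f = cfg.fam_weight
        if f == 0:
            return values
        tau_g = dict(zip(groups, rng.normal(size=len(groups))))
        tau_m = dict(zip(gmats, rng.normal(size=len(gmats))))
        scale = np.std(values) if np.std(values) > 0 else 1.0
        target = scale * np.array(
            [0.7 * tau_g[g] + 0.7 * tau_m[(g, m)]
             for g, m in zip(mem["group"], mem["matriline"])]
        )
        return (1.0 - f) * values + f * target

    offset = converge(cfg.sd_individual * signature(z_f0, 0))
    age = mem["age_years"].to_numpy(dtype=float)
    f0 = cfg.base_f0 + offset + cfg.age_slope * (age - age.mean())

    prof = mem[["id", "group", "matriline", "birth_year", "age_years"]].copy()
    prof["f0"] = f0
    prof["duration"] = cfg.duration_mean * np.exp(converge(0.5 * cfg.duration_cv * signature(z_dur, 1)))
    prof["arch_depth"] = np.clip(cfg.arch_depth * (1.0 + converge(0.3 * signature(z_arch, 2))), 0.02, 0.6)
    prof["tilt_db"] = cfg.spectral_tilt_db + converge(0.8 * signature(z_tilt, 3))
    prof["g"] = gvec
    return prof


def synthesize_call(
    profile: pd.Series,
    cfg: AcousticEffectConfig,
    call_index: int,
    rng: np.random.Generator | None = None,
) -> CallRecording:
    """Render one call for a female given her acoustic profile.

    The F0 contour is a raised-cosine arch: the call starts and ends at the
    per-call base F0 and peaks mid-call at ``(1 + arch_depth)`` times it.
    Harmonic k is attenuated by ``tilt_db * (k - 1)`` dB.  White noise is
    added at ``snr_db`` relative to the harmonic signal's RMS.
    """
    if rng is None:
        ident = zlib.crc32(str(profile["id"]).encode())  # stable across processes
        rng = np.random.default_rng([cfg.seed, ident, call_index])
    sr = cfg.sample_rate

    dur = float(profile["duration"]) * (1.0 + cfg.duration_cv * rng.normal())
    dur = max(dur, 0.0)
    n_samples = int(round(dur * sr))
    if n_samples <= 2 * 128:  # fewer than two analysis hops of signal
        raise DegenerateCallError(f"call duration {dur:.4f}s is degenerate")

    f0_call = float(profile["f0"]) * (1.0 + cfg.jitter_cv * rng.normal())
    depth = float(np.clip(profile["arch_depth"] * (1.0 + cfg.arch_jitter_cv * rng.normal()),
                          0.02, 0.6))
    tilt = float(profile["tilt_db"] + cfg.tilt_jitter_db * rng.normal())

    t = np.arange(n_samples) / sr
    contour = f0_call * (1.0 + depth * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / dur)))

    nyq_after_decimation = 11050 / 2.0
    if contour.max() * cfg.n_harmonics > nyq_after_decimation:
        warnings.warn("highest harmonics exceed the analysis band and will be clipped",
                      RuntimeWarning, stacklevel=2)

    phase = 2.0 * np.pi * np.cumsum(contour) / sr
    sig = np.zeros(n_samples)
    for k in range(1, cfg.n_harmonics + 1):
        if contour.max() * k >= 0.45 * sr:
            break
        amp = 10.0 ** (tilt * (k - 1) / 20.0)
        sig += amp * np.sin(k * phase)

    # cosine on/offset ramps to avoid clicks
    ramp = min(int(0.015 * sr), n_samples // 4)
    env = np.ones(n_samples)
    env[:ramp] = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    sig *= env

    rms = np.sqrt(np.mean(sig**2))
    noise_sd = rms * 10.0 ** (-cfg.snr_db / 20.0)
    sig = sig + rng.normal(0.0, noise_sd, size=n_samples)

    peak = np.max(np.abs(sig))
    if peak > 0:
        sig = 0.5 * sig / peak

    return CallRecording(
        call_id=f"{profile['id']}_{call_index:02d}",
        female_id=str(profile["id"]),
        sample_rate=sr,
        waveform=sig.astype(np.float64),
        group=str(profile["group"]),
        matriline=str(profile["matriline"]),
        birth_year=int(profile["birth_year"]),
        age_years=float(profile["age_years"]),
    )


def simulate_dataset(pop_cfg: PopulationConfig, ac_cfg: AcousticEffectConfig) -> SimulatedDataset:
    """Generate population, latent traits, and all calls."""
    ped, membership = generate_population(pop_cfg)
    latents = assign_latent_traits(ped, ac_cfg)
    profiles = female_profiles(membership, latents, ac_cfg)

    calls: list[CallRecording] = []
    for _, prof in profiles.iterrows():
        n_calls = int(membership.loc[membership["id"] == prof["id"], "n_calls"].iloc[0])
        for ci in range(n_calls):
            calls.append(synthesize_call(prof, ac_cfg, ci))

    truth = {
        "population": dataclasses.asdict(pop_cfg),
        "acoustics": dataclasses.asdict(ac_cfg),
        "n_calls_total": len(calls),
    }
    return SimulatedDataset(pedigree=ped, membership=membership, calls=calls, truth=truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write WAVs (PCM 16, mono), calls.csv, pedigree.csv and truth.json."""
    outdir = Path(outdir)
    wavdir = outdir / "wav"
    wavdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for call in ds.calls:
        path = wavdir / f"{call.call_id}.wav"
        pcm = np.clip(call.waveform, -1.0, 1.0)
        wavfile.write(path, call.sample_rate, (pcm * 32767).astype(np.int16))
        rows.append(dict(
            call_id=call.call_id, female_id=call.female_id,
            wav_path=str(path.relative_to(outdir)),
            group=call.group, matriline=call.matriline,
            birth_year=call.birth_year, age_years=call.age_years,
        ))
    pd.DataFrame(rows).to_csv(outdir / "calls.csv", index=False)
    ds.pedigree.to_csv(outdir / "pedigree.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=2, default=str)


def scenario_config(
    name: str, seed: int = 0, **overrides
) -> tuple[PopulationConfig, AcousticEffectConfig]:
    """Named study conditions.

    * ``paper_like``  — no heritable acoustic component, familiarity-driven
      convergence, and an age trend (the configuration whose downstream
      analysis should find familiarity and age but not kinship).
    * ``kin_effect``  — dominant heritable component (kin correlation
      0.96 r), no familiarity convergence, no age trend.
    * ``null``        — individual signatures only.
    """
    pop = PopulationConfig(seed=seed)
    if name == "paper_like":
        ac = AcousticEffectConfig(h2_weight=0.0, fam_weight=0.6, age_slope=3.0, seed=seed)
    elif name == "kin_effect":
        ac = AcousticEffectConfig(h2_weight=5.0, fam_weight=0.0, age_slope=0.0, seed=seed)
    elif name == "null":
        ac = AcousticEffectConfig(h2_weight=0.0, fam_weight=0.0, age_slope=0.0, seed=seed)
    else:
        raise InvalidConfigError(f"unknown scenario {name!r}")
    pop_over = {k[4:]: v for k, v in overrides.items() if k.startswith("pop_")}
    ac_over = {k[3:]: v for k, v in overrides.items() if k.startswith("ac_")}
    pop = dataclasses.replace(pop, **pop_over)
    ac = dataclasses.replace(ac, **ac_over)
    return pop, ac
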