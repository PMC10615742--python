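"""Synthetic actigraphy and lipidomics with known ground truth.

The generators emulate the statistical structure the detectors and tests
assume — nocturnal negative-binomial wheel counts on a 12:12 light/dark
cycle with injected hyperactivity bouts and multi-week hypoactivity episodes,
and log-normal lipid abundances with group effects of specified Cohen's d
concentrated in chosen lipid classes or fatty acids — so that every pipeline
stage can be verified against injected truth.  All randomness flows from a
single integer seed; regeneration is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import ActivitySeries, write_activity_csv
from .lipidomics import LipidTable

__all__ = [
    "EpisodeSpec",
    "ActivitySimConfig",
    "LipidEffect",
    "LipidomicsSimConfig",
    "simulate_activity",
    "simulate_lipidomics",
    "draw_spontaneous_habs",
    "write_fixture_bundle",
    "DEFAULT_CLASS_COMPOSITION",
    "DEFAULT_ACYL_POOL",
]


# ---------------------------------------------------------------------------
# actigraphy


@dataclass(frozen=True)
class EpisodeSpec:
    """An injected episode.

    HABs are 6-24 h of sustained high running at ``amplitude`` times the
    dark-phase rate (manic animals run at night-like intensity around the
    clock, including the light phase).  Depression-like episodes multiply
    the circadian rate profile by ``amplitude`` (< 1) for >= 14 days and move
    ``light_redistribution`` of the remaining expected activity into the
    first 6 h of the light phase (the circadian phase-delay signature).
    """

    kind: str  # "HAB" or "DEPRESSION_LIKE"
    onset_day: int
    onset_hour: float = 0.0  # HAB only, ZT hours
    duration_hours: float = 12.0  # HAB
    duration_days: int = 21  # DEPRESSION_LIKE
    amplitude: float = 5.0
    light_redistribution: float = 0.0  # DEPRESSION_LIKE

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.kind == "HAB" and not 6.0 <= self.duration_hours <= 24.0:
            raise ValueError("HAB duration must lie in [6, 24] hours")
        if self.kind == "DEPRESSION_LIKE" and self.duration_days < 14:
            raise ValueError("depression-like episodes last >= 14 days")
        if not 0.0 <= self.light_redistribution < 1.0:
            raise ValueError("light_redistribution must lie in [0, 1)")

    def bin_span(self, bins_per_day: int, bin_minutes: int) -> tuple[int, int]:
        """Half-open [start, end) bin range of the episode."""
        if self.kind == "HAB":
            start = self.onset_day * bins_per_day + int(
                round(self.onset_hour * 60.0 / bin_minutes)
            )
            end = start + int(round(self.duration_hours * 60.0 / bin_minutes))
        else:
            start = self.onset_day * bins_per_day
            end = start + self.duration_days * bins_per_day
        return start, end


@dataclass
class ActivitySimConfig:
    """Cohort-free single-animal actigraphy generator settings.

    Defaults model a C57BL/6-style nocturnal runner on 12:12 LD in 6-min
    bins: ~50 revolutions per dark bin (~6000/night) against a small light-
    phase trickle, negative-binomial bin noise (``dispersion`` = NB size k,
    var = mu + mu^2/k) plus a day-level log-normal factor for day-to-day
    variability.
    """

    n_days: int = 183
    bin_minutes: int = 6
    dark_mean: float = 50.0
    light_mean: float = 2.0
    dispersion: float = 10.0
    day_sigma: float = 0.15
    light_hours: float = 12.0
    episodes: list[EpisodeSpec] = field(default_factory=list)
    distribution: str = "nb"  # or "poisson"
    waveform: str = "square"  # or "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dark_mean > self.light_mean >= 0:
            raise ValueError("nocturnal profile requires dark_mean > light_mean >= 0")
        if self.distribution not in ("nb", "poisson"):
            raise ValueError("distribution must be 'nb' or 'poisson'")
        if self.waveform not in ("square", "cosine"):
            raise ValueError("waveform must be 'square' or 'cosine'")


def _phase_profile(cfg: ActivitySimConfig) -> np.ndarray:
    """Expected counts per bin over one day (bin 0 = ZT0 = lights-on)."""
    bpd = 1440 // cfg.bin_minutes
    zt = np.arange(bpd) * cfg.bin_minutes / 60.0
    if cfg.waveform == "square":
        return np.where(zt < cfg.light_hours, cfg.light_mean, cfg.dark_mean)
    # cosine ramp peaking mid-dark-phase, same min/max as the square wave
    mid_dark = cfg.light_hours + (24.0 - cfg.light_hours) / 2.0
    c = 0.5 * (1 + np.cos(2 * np.pi * (zt - mid_dark) / 24.0))
    return cfg.light_mean + (cfg.dark_mean - cfg.light_mean) * c


def simulate_activity(
    cfg: ActivitySimConfig, subject_id: str = "sim", **series_kwargs
) -> tuple[ActivitySeries, list[EpisodeSpec]]:
    """Generate one animal's series plus the injected ground-truth episodes."""
    rng = np.random.default_rng(cfg.seed)
    bpd = 1440 // cfg.bin_minutes
    n_bins = cfg.n_days * bpd
    mu = np.tile(_phase_profile(cfg), cfg.n_days).astype(float)

    # overlap check within kind
    for kind in ("HAB", "DEPRESSION_LIKE"):
        spans = sorted(
            s.bin_span(bpd, cfg.bin_minutes) for s in cfg.episodes if s.kind == kind
        )
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping {kind} episode specs")

    zt = (np.arange(n_bins) * cfg.bin_minutes / 60.0) % 24.0
    for spec in cfg.episodes:
        a, b = spec.bin_span(bpd, cfg.bin_minutes)
        a, b = max(a, 0), min(b, n_bins)
        if a >= b:
            raise ValueError("episode spec falls outside the recording")
        if spec.kind == "HAB":
            mu[a:b] = spec.amplitude * cfg.dark_mean
        else:
            seg = mu[a:b] * spec.amplitude
            if spec.light_redistribution > 0:
                morning = zt[a:b] < 6.0
                n_morning = int(morning.sum())
                moved = spec.light_redistribution * seg.sum()
                seg = seg * (1.0 - spec.light_redistribution)
                if n_morning:
                    seg[morning] += moved / n_morning
            mu[a:b] = seg

    day_factor = np.repeat(
        rng.lognormal(mean=-0.5 * cfg.day_sigma**2, sigma=cfg.day_sigma, size=cfg.n_days),
        bpd,
    )
    mu = mu * day_factor
    if cfg.distribution == "poisson":
        counts = rng.poisson(mu).astype(float)
    else:
        k = cfg.dispersion
        # NB via gamma-Poisson mixture keeps the mean exact for vector mu
        counts = rng.poisson(rng.gamma(shape=k, scale=mu / k)).astype(float)
    series = ActivitySeries(
        subject_id=subject_id,
        counts=counts,
        bin_minutes=cfg.bin_minutes,
        light_hours=cfg.light_hours,
        **series_kwargs,
    )
    return series, list(cfg.episodes)


def draw_spontaneous_habs(
    rng: np.random.Generator,
    n_days: int,
    hazard_per_day: float,
    amplitude: float = 5.0,
    refractory_days: int = 3,
) -> list[EpisodeSpec]:
    """Draw spontaneous hyperactivity bouts from a per-day hazard, with
    uniform 6-24 h durations and dark-phase onsets, so cohort frequency
    statistics have ground truth without hard-coding detector answers."""
    specs: list[EpisodeSpec] = []
    day = 1
    while day < n_days - 2:
        if rng.random() < hazard_per_day:
            dur = float(rng.uniform(6.0, 24.0))
            onset_hour = float(rng.uniform(12.0, 24.0 - 1e-9))
            specs.append(
                EpisodeSpec(
                    kind="HAB",
                    onset_day=day,
                    onset_hour=onset_hour,
                    duration_hours=dur,
                    amplitude=amplitude,
                )
            )
            day += refractory_days + int(math.ceil(dur / 24.0))
        else:
            day += 1
    return specs


# ---------------------------------------------------------------------------
# lipidomics

# A 26-class composition summing to 464 lipids, weighted toward the
# glycerophospholipid classes that dominate brain lipidomes.
DEFAULT_CLASS_COMPOSITION: dict[str, int] = {
    "PC": 60, "PE": 48, "PE(P)": 26, "PE(O)": 14, "PS": 28, "PI": 22,
    "PG": 12, "PA": 10, "LPC": 14, "LPE": 10, "LPS": 6, "LPI": 6,
    "SM": 30, "Cer": 24, "HexCer": 18, "SHexCer": 10, "ST": 8,
    "DG": 16, "TG": 46, "CL": 12, "BMP": 8, "CE": 8, "FA": 12,
    "MG": 6, "LPG": 5, "GM3": 5,
}
assert sum(DEFAULT_CLASS_COMPOSITION.values()) == 464
assert len(DEFAULT_CLASS_COMPOSITION) == 26

# 29 acyl chains ("C:D") with sampling weights favouring the abundant ones.
DEFAULT_ACYL_POOL: dict[str, float] = {
    "14:0": 2, "15:0": 1, "16:0": 10, "16:1": 4, "17:0": 1, "17:1": 1,
    "18:0": 9, "18:1": 10, "18:2": 6, "18:3": 2, "19:0": 1, "20:0": 2,
    "20:1": 4, "20:2": 2, "20:3": 3, "20:4": 7, "20:5": 3, "21:0": 1,
    "22:0": 2, "22:1": 2, "22:2": 1, "22:4": 3, "22:5": 3, "22:6": 8,
    "23:0": 1, "24:0": 3, "24:1": 4, "26:0": 1, "26:1": 1,
}
assert len(DEFAULT_ACYL_POOL) == 29

_MONOACYL_CLASSES = {"LPC", "LPE", "LPS", "LPI", "LPG", "CE", "FA", "MG", "ST", "GM3"}
_TRIACYL_CLASSES = {"TG"}
_TETRAACYL_CLASSES = {"CL"}


@dataclass(frozen=True)
class LipidEffect:
    """A group effect of standardized size ``d_target`` (on the log scale)
    applied to a lipid class, a fatty acid, or an explicit lipid-id set."""

    target: str | tuple  # class name, "FA:16:0", or tuple of lipid ids
    d_target: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.d_target < 0:
            raise ValueError("d_target must be nonnegative")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class LipidomicsSimConfig:
    n_lipids: int = 464
    class_composition: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COMPOSITION))
    acyl_pool: dict = field(default_factory=lambda: dict(DEFAULT_ACYL_POOL))
    group_sizes: tuple[int, int] = (8, 8)
    lognormal_sigma: float = 0.4
    base_logmean: float = 10.0
    base_spread: float = 2.0
    effects: list[LipidEffect] = field(default_factory=list)
    group_factor: str = "genotype"
    group_levels: tuple[str, str] = ("WT", "MUT")
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_composition.values()) != self.n_lipids:
            raise ValueError("class composition must sum to n_lipids")


def _n_chains(lipid_class: str) -> int:
    if lipid_class in _MONOACYL_CLASSES:
        return 1
    if lipid_class in _TRIACYL_CLASSES:
        return 3
    if lipid_class in _TETRAACYL_CLASSES:
        return 4
    return 2


def _effect_members(effect: LipidEffect, lipids: pd.DataFrame) -> np.ndarray:
    if isinstance(effect.target, tuple):
        mask = lipids.index.isin(effect.target)
    elif isinstance(effect.target, str) and effect.target.startswith("FA:"):
        chain = effect.target[3:]
        mask = lipids["acyl_chains"].map(lambda ch: chain in ch).to_numpy()
    else:
        mask = (lipids["lipid_class"] == effect.target).to_numpy()
    if not mask.any():
        raise ValueError(f"effect target {effect.target!r} matches no lipids")
    return mask


def simulate_lipidomics(cfg: LipidomicsSimConfig) -> tuple[LipidTable, pd.DataFrame]:
    """Generate a LipidTable plus a per-lipid ground-truth effect table.

    Abundances are log-normal: per-lipid baseline log2-mean drawn from
    N(base_logmean, base_spread), within-group log2 noise sd
    ``lognormal_sigma``; each effect shifts its member lipids by
    direction * d_target * lognormal_sigma in log2 space for the second
    group, so the population Cohen's d on the log scale equals d_target.
    """
    rng = np.random.default_rng(cfg.seed)
    chains = sorted(cfg.acyl_pool)
    weights = np.array([cfg.acyl_pool[c] for c in chains], dtype=float)
    weights /= weights.sum()

    rows = []
    for cls in sorted(cfg.class_composition):
        for _ in range(cfg.class_composition[cls]):
            k = _n_chains(cls)
            ch = sorted(rng.choice(chains, size=k, replace=True, p=weights))
            rows.append((cls, tuple(ch)))
    lipid_ids = []
    seen: dict[str, int] = {}
    for cls, ch in rows:
        base = f"{cls} {'_'.join(ch)}"
        seen[base] = seen.get(base, 0) + 1
        lipid_ids.append(base if seen[base] == 1 else f"{base} [{seen[base]}]")
    lipids = pd.DataFrame(
        {
            "lipid_class": [cls for cls, _ in rows],
            "acyl_chains": [list(ch) for _, ch in rows],
        },
        index=pd.Index(lipid_ids, name="lipid_id"),
    )

    n_a, n_b = cfg.group_sizes
    sample_ids = [f"{cfg.group_levels[0]}_{i+1}" for i in range(n_a)] + [
        f"{cfg.group_levels[1]}_{i+1}" for i in range(n_b)
    ]
    samples = pd.DataFrame(
        {
            cfg.group_factor: [cfg.group_levels[0]] * n_a + [cfg.group_levels[1]] * n_b,
            "diet": "chow",
            "sex": "male",
            "tissue": "brain",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    base = rng.normal(cfg.base_logmean, cfg.base_spread, size=cfg.n_lipids)
    log2 = base[:, None] + rng.normal(
        0.0, cfg.lognormal_sigma, size=(cfg.n_lipids, n_a + n_b)
    )
    shift = np.zeros(cfg.n_lipids)
    for eff in cfg.effects:
        mask = _effect_members(eff, lipids)
        shift[mask] += eff.direction * eff.d_target * cfg.lognormal_sigma
    log2[:, n_a:] += shift[:, None]
    abundance = pd.DataFrame(2.0**log2, index=lipids.index, columns=samples.index)

    truth = pd.DataFrame(
        {
            "true_log2_shift": shift,
            "true_d": np.abs(shift) / cfg.lognormal_sigma,
            "is_effect": shift != 0,
        },
        index=lipids.index,
    )
    return LipidTable(abundance=abundance, lipids=lipids, samples=samples), truth


# ---------------------------------------------------------------------------
# fixture bundles


def write_fixture_bundle(
    out_dir,
    activity_configs: dict[str, ActivitySimConfig] | None = None,
    lipid_config: LipidomicsSimConfig | None = None,
) -> dict:
    """Write CSV/TSV fixtures plus a JSON manifest of seeds and ground truth.

    Regenerating from the manifest's recorded configs yields byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"activity": {}, "lipidomics": None}
    for subject_id, cfg in (activity_configs or {}).items():
        series, truth = simulate_activity(cfg, subject_id=subject_id)
        path = out / f"{subject_id}.activity.csv"
        write_activity_csv(series, path)
        manifest["activity"][subject_id] = {
            "path": path.name,
            "seed": cfg.seed,
            "n_days": cfg.n_days,
            "episodes": [asdict(s) for s in truth],
        }
    if lipid_config is not None:
        table, truth = simulate_lipidomics(lipid_config)
        table.write(out / "lipids")
        truth.to_csv(out / "lipids.truth.tsv", sep="\t")
        manifest["lipidomics"] = {
            "seed": lipid_config.seed,
            "n_lipids": lipid_config.n_lipids,
            "n_effects": int(truth["is_effect"].sum()),
            "effect_lipids": truth.index[truth["is_effect"]].tolist(),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
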