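"""Seeded synthetic study generator.

Generates the three assay tables an in-vitro ozone-exposure study
produces — per-well viability luminescence (RLU), per-slide CBMN scoring
counts, and per-cell comet measurements — with the effect sizes observed
for A549 adenocarcinoma cells and Hs27 fibroblasts exposed to 120 ppb
ozone: a ~21.5% viability deficit at 24 h resolving by 48 h, a
72-vs-48 h viability drop of ~26% (treated) vs ~50% (control),
Replication-Index deficits of ~11% (48 h) and ~6% (72 h), a ~2-fold
micronucleus induction, and comet tail-DNA / Olive-Tail-Moment group
means matching the study's printed values.

Every generator is a pure function of (design, profile, seed): identical
inputs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "EffectProfile",
    "default_profile",
    "null_profile",
    "gen_viability",
    "gen_mn_scores",
    "gen_comet_cells",
    "gen_study",
]

VIABILITY_TIMES_H = (0.0, 24.0, 48.0, 72.0)
GENOTOX_TIMES_H = (48.0, 72.0)

#: Scoring ceiling: micronuclei counted per binucleated cell.
_MN_CEILING = 6


@dataclass(frozen=True)
class StudyDesign:
    """Experimental layout: which cultures exist and how often.

    ``n_replicates`` biological replicates, each measured in
    ``n_technical`` technical replicates (wells for viability, slides for
    CBMN and comet scoring); the study ran three biological replicates in
    triplicate.
    """

    cell_line: str = "A549"
    conditions: tuple[str, ...] = ("control", "ozone")
    viability_times_h: tuple[float, ...] = VIABILITY_TIMES_H
    genotox_times_h: tuple[float, ...] = GENOTOX_TIMES_H
    n_replicates: int = 3
    n_technical: int = 3
    cells_per_slide: int = 300
    bn_scored_per_slide: int = 1000

    def __post_init__(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("design requires at least 3 biological replicates")
        if self.n_technical < 1 or self.cells_per_slide < 1:
            raise ValueError("technical replicates and cells per slide must be >= 1")


@dataclass(frozen=True)
class EffectProfile:
    """Effect sizes and noise levels the generator reproduces.

    Viability deficits are fractions of the control mean at each time
    point (applied at 0-48 h); the treated 72 h mean is derived from
    ``treated_7248_drop`` applied to the treated 48 h mean, the control
    72 h mean from ``control_7248_drop``.  ``ri_deficit`` scales the
    treated proliferation fraction, ``mn_fold`` the treated micronucleus
    rate, and ``comet_means`` fixes per-group (tail DNA %, OTM) targets.
    """

    viability_deficit_by_time: dict[float, float]
    control_7248_drop: float
    treated_7248_drop: float
    ri_deficit: dict[float, float]
    mn_fold: dict[float, float]
    comet_means: dict[tuple[float, str], tuple[float, float]]
    noise_cv: float = 0.05
    control_shape: dict[float, float] = field(
        default_factory=lambda: {0.0: 1.0, 24.0: 2.2, 48.0: 3.6}
    )
    mn_base_rate_per_1000: float = 12.5
    nucleation_fractions: tuple[float, float, float, float] = (0.30, 0.55, 0.08, 0.07)

    def __post_init__(self) -> None:
        for t, d in self.viability_deficit_by_time.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"viability deficit {d} at {t} h outside [0, 1]")
        for name, v in (
            ("control_7248_drop", self.control_7248_drop),
            ("treated_7248_drop", self.treated_7248_drop),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for t, d in self.ri_deficit.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"RI deficit {d} at {t} h outside [0, 1]")
        for t, f in self.mn_fold.items():
            if f < 0:
                raise ValueError(f"MN fold {f} at {t} h negative")
        for (t, cond), (pct, otm) in self.comet_means.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(
                    f"comet tail-DNA mean {pct} for ({t} h, {cond}) outside [0, 100]"
                )
            if otm < 0:
                raise ValueError(f"negative OTM target for ({t} h, {cond})")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if abs(sum(self.nucleation_fractions) - 1.0) > 1e-9:
            raise ValueError("nucleation fractions must sum to 1")


def default_profile(cell_line: str = "A549") -> EffectProfile:
    """Study-calibrated effect profile for one cell line.

    A549 carries the full ozone response; Hs27 shows no viability or RI
    effect, micronucleus induction at 72 h only, and a milder comet
    response at 72 h only.
    """
    if cell_line == "A549":
        return EffectProfile(
            viability_deficit_by_time={0.0: 0.0, 24.0: 0.215, 48.0: 0.0},
            control_7248_drop=0.50,
            treated_7248_drop=0.26,
            ri_deficit={48.0: 0.11, 72.0: 0.06},
            mn_fold={48.0: 2.0, 72.0: 1.0},
            comet_means={
                (48.0, "control"): (2.88, 1.3),
                (48.0, "ozone"): (8.3, 4.1),
                (72.0, "control"): (3.7, 1.8),
                (72.0, "ozone"): (7.3, 4.4),
            },
        )
    if cell_line == "Hs27":
        return EffectProfile(
            viability_deficit_by_time={0.0: 0.0, 24.0: 0.0, 48.0: 0.0},
            control_7248_drop=0.0,
            treated_7248_drop=0.0,
            ri_deficit={48.0: 0.0, 72.0: 0.0},
            mn_fold={48.0: 1.0, 72.0: 2.0},
            comet_means={
                (48.0, "control"): (3.3, 1.38),
                (48.0, "ozone"): (3.3, 1.38),
                (72.0, "control"): (3.3, 1.38),
                (72.0, "ozone"): (5.9, 2.2),
            },
            # fibroblasts grow more slowly and plateau rather than crash
            control_shape={0.0: 1.0, 24.0: 1.6, 48.0: 2.4},
        )
    raise ValueError(f"no default profile for cell line {cell_line!r}")


def null_profile(cell_line: str = "A549") -> EffectProfile:
    """A profile with no treatment effect anywhere (for type-I studies)."""
    base = default_profile(cell_line)
    times = GENOTOX_TIMES_H
    ctrl_means = {t: base.comet_means[(t, "control")] for t in times}
    return replace(
        base,
        viability_deficit_by_time={t: 0.0 for t in base.viability_deficit_by_time},
        treated_7248_drop=base.control_7248_drop,
        ri_deficit={t: 0.0 for t in times},
        mn_fold={t: 1.0 for t in times},
        comet_means={(t, c): ctrl_means[t] for t in times for c in ("control", "ozone")},
    )


def _viability_targets(
    design: StudyDesign, profile: EffectProfile
) -> dict[tuple[str, float], float]:
    """Group-mean RLU targets (normalised units: control t=0 mean = 1)."""
    shape = dict(profile.control_shape)
    if 48.0 not in shape:
        raise ValueError("control_shape must include the 48 h mean")
    control = {t: shape[t] for t in design.viability_times_h if t in shape}
    control[72.0] = shape[48.0] * (1.0 - profile.control_7248_drop)
    missing = set(design.viability_times_h) - set(control)
    if missing:
        raise ValueError(f"control_shape missing time points {sorted(missing)}")
    treated = {
        t: control[t] * (1.0 - profile.viability_deficit_by_time.get(t, 0.0))
        for t in design.viability_times_h
        if t != 72.0
    }
    treated[72.0] = treated[48.0] * (1.0 - profile.treated_7248_drop)
    targets = {("control", t): control[t] for t in design.viability_times_h}
    targets.update({("ozone", t): treated[t] for t in design.viability_times_h})
    return targets


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_viability(
    design: StudyDesign, profile: EffectProfile, seed: int
) -> pd.DataFrame:
    """Per-well viability (RLU) table.

    Columns: ``cell_line, condition, time_h, replicate, well, rlu``.
    RLU is in normalised units (control 0 h mean = 1); group means equal
    the profile targets in expectation.
    """
    rng = np.random.default_rng(seed)
    targets = _viability_targets(design, profile)
    rows = []
    n_wells = design.n_replicates * design.n_technical
    for cond in design.conditions:
        for t in design.viability_times_h:
            mean = targets[(cond, t)]
            noise = _lognormal_factors(rng, profile.noise_cv, n_wells)
            i = 0
            for rep in range(1, design.n_replicates + 1):
                for well in range(1, design.n_technical + 1):
                    rows.append(
                        {
                            "cell_line": design.cell_line,
                            "condition": cond,
                            "time_h": t,
                            "replicate": rep,
                            "well": well,
                            "rlu": mean * noise[i],
                        }
                    )
                    i += 1
    return pd.DataFrame(rows)


def _treated_nucleation(
    fractions: tuple[float, float, float, float], deficit: float
) -> tuple[float, float, float, float]:
    """Scale bi/multinucleate fractions so the expected Replication Index
    is 100 x (1 - deficit); the mass removed returns to the mononucleated
    class."""
    mono, bi, tri, tetra = fractions
    s = 1.0 - deficit
    bi_t, tri_t, tetra_t = s * bi, s * tri, s * tetra
    mono_t = 1.0 - bi_t - tri_t - tetra_t
    return (mono_t, bi_t, tri_t, tetra_t)


def gen_mn_scores(
    design: StudyDesign, profile: EffectProfile, seed: int
) -> pd.DataFrame:
    """Per-slide CBMN scoring table.

    Columns: ``slide_id, cell_line, condition, time_h, n_mono, n_bi,
    n_tri, n_tetra, n_total, n_bn_scored, n_mn``.  Nucleation counts are
    multinomial over mono/bi/tri/tetra with treated fractions scaled so
    the expected RI is 100 x (1 - ri_deficit); micronuclei are binomial
    with the treated rate equal to control rate x mn_fold.
    """
    rng = np.random.default_rng(seed)
    base_rate = profile.mn_base_rate_per_1000 / 1000.0
    rows = []
    for cond in design.conditions:
        for t in design.genotox_times_h:
            deficit = profile.ri_deficit.get(t, 0.0) if cond != "control" else 0.0
            fold = profile.mn_fold.get(t, 1.0) if cond != "control" else 1.0
            fracs = (
                _treated_nucleation(profile.nucleation_fractions, deficit)
                if deficit > 0
                else profile.nucleation_fractions
            )
            mn_rate = base_rate * fold
            if mn_rate > _MN_CEILING:
                raise ValueError(
                    f"mn_fold {fold} at {t} h drives the expected MN per "
                    f"binucleated cell above the scoring ceiling"
                )
            for rep in range(1, design.n_replicates + 1):
                n_total = design.bn_scored_per_slide
                counts = rng.multinomial(n_total, fracs)
                n_bn = design.bn_scored_per_slide
                n_mn = int(rng.binomial(n_bn, min(mn_rate, 1.0)))
                rows.append(
                    {
                        "slide_id": f"{design.cell_line}-{cond}-{t:g}h-r{rep}",
                        "cell_line": design.cell_line,
                        "condition": cond,
                        "time_h": t,
                        "n_mono": int(counts[0]),
                        "n_bi": int(counts[1]),
                        "n_tri": int(counts[2]),
                        "n_tetra": int(counts[3]),
                        "n_total": int(n_total),
                        "n_bn_scored": n_bn,
                        "n_mn": n_mn,
                    }
                )
    return pd.DataFrame(rows)


#: Beta concentration for per-cell tail-DNA fractions; low values give the
#: right-skewed shapes comet data show.
_TAIL_BETA_CONCENTRATION = 5.0
#: CV of the log-normal length measurements.
_LENGTH_CV = 0.30
#: Tail length relative to the centroid distance (tails extend past their
#: intensity centroid).
_TAIL_LENGTH_RATIO = 1.5


def gen_comet_cells(
    design: StudyDesign, profile: EffectProfile, seed: int
) -> pd.DataFrame:
    """Per-cell comet table.

    Columns: ``cell_id, slide_id, cell_line, condition, time_h,
    tail_dna_pct, tail_length, centroid_distance``.  Tail-DNA percent is
    Beta-distributed on [0, 100] with the profile's group mean; lengths
    are log-normal with the centroid distance scaled so the expected
    Olive Tail Moment (tail% x distance / 100) hits the profile target.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in design.conditions:
        for t in design.genotox_times_h:
            try:
                pct_mean, otm_mean = profile.comet_means[(t, cond)]
            except KeyError:
                raise ValueError(f"no comet means for ({t} h, {cond!r})") from None
            m = pct_mean / 100.0
            for rep in range(1, design.n_replicates + 1):
                slide = f"{design.cell_line}-{cond}-{t:g}h-r{rep}"
                n = design.cells_per_slide
                if m <= 0.0:
                    pct = np.zeros(n)
                else:
                    a = m * _TAIL_BETA_CONCENTRATION
                    b = (1.0 - m) * _TAIL_BETA_CONCENTRATION
                    pct = 100.0 * rng.beta(a, b, size=n)
                # independent lengths: E[OTM] = E[pct] * E[dist] / 100
                dist_mean = (100.0 * otm_mean / pct_mean) if pct_mean > 0 else 0.0
                dist = dist_mean * _lognormal_factors(rng, _LENGTH_CV, n)
                length = (
                    _TAIL_LENGTH_RATIO
                    * dist_mean
                    * _lognormal_factors(rng, _LENGTH_CV, n)
                )
                for i in range(n):
                    rows.append(
                        {
                            "cell_id": f"{slide}-c{i + 1}",
                            "slide_id": slide,
                            "cell_line": design.cell_line,
                            "condition": cond,
                            "time_h": t,
                            "tail_dna_pct": float(pct[i]),
                            "tail_length": float(length[i]),
                            "centroid_distance": float(dist[i]),
                        }
                    )
    return pd.DataFrame(rows)


def gen_study(
    cell_line: str = "A549",
    seed: int = 0,
    design: StudyDesign | None = None,
    profile: EffectProfile | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate the full three-table bundle for one cell line.

    Sub-generators draw from independent streams derived from ``seed`` so
    each table is individually reproducible.
    """
    if design is None:
        design = StudyDesign(cell_line=cell_line)
    if profile is None:
        profile = default_profile(cell_line)
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    return {
        "viability": gen_viability(design, profile, seeds[0]),
        "cbmn": gen_mn_scores(design, profile, seeds[1]),
        "comet": gen_comet_cells(design, profile, seeds[2]),
    }
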