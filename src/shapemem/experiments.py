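"""Ensemble driver: in-silico division experiments and unit calibration.

One replicate is the full shape-memory pipeline: embed a fixture of known
eccentricity A_long in a lattice, load blue (cortical force generator) and
yellow (Delta) particles on its boundary with the distance-cubed rule, run
mitotic rounding under the Potts dynamics until the surface trigger fires,
divide perpendicular to the cell vector, partition the yellow particles
between the daughters, and resolve the V2a/V2b fates with the
lateral-inhibition ODE.  The headline readout per shape is the fraction of
replicates in which the daughter on the (+) side of the original long axis
acquires the V2a fate, tested against the 50:50 null with a chi-squared
goodness-of-fit test.

The ensembles mirror the published in-silico experiments: the six-shape
division ensemble (bias vs A_long), the no-polarization control (uniform
yellow initialization), the diffusion sweep (yellow step 0 / 2 / 4), the
abundance sweep (concentration-to-diffusion ratios 0.0025 / 0.025 / 0.25),
and the long-axis-rule statistics of the division orientation.  The desk
scale is 48 replicates per shape; the published scale (144) is a flag away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import particles as pt
from ._engine import STATUS_DIVIDED, simulate_rounding
from .cpm import CPMParams, Lattice, divide_cell, sphere_target_surface
from .fate import FateParams, initial_conditions, resolve_fate
from .synthetic_shapes import PAPER_ALONG_TARGETS, ShapeFixture, tune_to_target

__all__ = [
    "EnsembleConfig",
    "ReplicateResult",
    "EnsembleResult",
    "run_single_division",
    "run_division_ensemble",
    "chi_square_gof",
    "long_axis_rule_stats",
    "sweep_delta_dynamics",
    "calibrate_units",
    "fit_mode",
    "build_fixtures",
]


@dataclass
class EnsembleConfig:
    """Study conditions for a division ensemble."""

    a_long_targets: tuple = PAPER_ALONG_TARGETS
    replicates: int = 48                  # published scale: 144
    conc_yellow: float = 0.05             # particles per cell lattice site
    conc_blue: float = 0.05
    conc_basis: str = "cell_sites"        # or "boundary_sites"
    step_yellow: float = 2.0              # lattice lengths per mcs
    step_blue: float = 1.0
    init_mode_yellow: str = "shape_weighted"   # or "uniform"
    base_seed: int = 0
    margin: int = 6                       # medium margin around the fixture
    cpm: CPMParams = field(default_factory=CPMParams)
    fate: FateParams = field(default_factory=FateParams)

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.init_mode_yellow not in ("shape_weighted", "uniform"):
            raise ValueError(f"unknown init mode {self.init_mode_yellow!r}")
        if self.conc_basis not in ("cell_sites", "boundary_sites"):
            raise ValueError(f"unknown concentration basis {self.conc_basis!r}")


@dataclass
class ReplicateResult:
    """Outcome of one in-silico division."""

    divided: bool
    div_mcs: int
    n_yellow: int
    n_blue: int
    n_plus: int = 0                 # yellow received by the (+)-side daughter
    n_minus: int = 0
    angle_cv_along: float = float("nan")   # division axis vs a_long, deg [0, 90]
    plus_fate: str = "unresolved"   # fate of the (+)-side daughter
    resolved: bool = False
    fate_mcs: int | None = None
    flags: list = field(default_factory=list)


@dataclass
class EnsembleResult:
    """Per-shape fate counts, division-axis angles and chi-squared tests."""

    table: pd.DataFrame             # one row per replicate
    summary: pd.DataFrame           # one row per shape
    config: EnsembleConfig


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def run_single_division(
    fixture: ShapeFixture,
    config: EnsembleConfig,
    seed: int,
) -> ReplicateResult:
    """Run one full rounding-division-fate replicate, fully seeded."""
    ss = np.random.SeedSequence(seed)
    rng_init, rng_div, rng_fate = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    kernel_seed = int(ss.generate_state(1)[0]) & 0x7FFFFFFF

    lat = Lattice.from_mask(
        fixture.mask.mask, margin=config.margin,
        side_length_um=config.cpm.side_length_um,
    )
    v0 = lat.volumes[1]
    s_target = sphere_target_surface(v0, config.cpm.surface_correction)
    # particle counts: concentration x cell sites reproduces the published
    # ~80-160 particles per cell at 2.5-5.0e-2 per lattice site
    basis = v0 if config.conc_basis == "cell_sites" else len(
        pt.boundary_sites(lat, 1)
    )
    n_blue = max(1, round(config.conc_blue * basis))
    n_yellow = max(1, round(config.conc_yellow * basis))

    blue = pt.init_particles_shape_weighted(
        lat, 1, n_blue, rng_init, color=pt.BLUE, step=config.step_blue
    )
    if config.init_mode_yellow == "shape_weighted":
        yellow = pt.init_particles_shape_weighted(
            lat, 1, n_yellow, rng_init, color=pt.YELLOW, step=config.step_yellow
        )
    else:
        yellow = pt.init_particles_uniform(
            lat, 1, n_yellow, rng_init, color=pt.YELLOW, step=config.step_yellow
        )

    res = simulate_rounding(
        lat.cell_ids, blue.positions, yellow.positions,
        config.step_blue, config.step_yellow,
        config.cpm.j_cell_medium, config.cpm.lambda_v, config.cpm.lambda_s,
        config.cpm.temperature,
        v0, s_target, config.cpm.s_division_factor * s_target,
        config.cpm.total_mcs, kernel_seed,
    )
    out = ReplicateResult(
        divided=(res["status"] == STATUS_DIVIDED),
        div_mcs=res["mcs"],
        n_yellow=n_yellow,
        n_blue=n_blue,
    )
    if res["status"] != STATUS_DIVIDED:
        out.flags.append(
            "no_division" if res["status"] == 1 else "cell_annihilated"
        )
        return out

    rounded = Lattice(res["cell_ids"], config.cpm.side_length_um)
    c_mass = rounded.centroid(1)
    cv = pt.cell_vector(res["blue_positions"], c_mass)
    if np.linalg.norm(cv) < 1e-9:
        # degenerate: blue particles cancel; random plane, flagged
        out.flags.append("zero_cell_vector")
        cv = _unit(rng_div.standard_normal(3))
    a_long = _unit(np.asarray(fixture.descriptor.a_long, dtype=float))
    cos_line = abs(float(np.dot(_unit(cv), a_long)))
    out.angle_cv_along = math.degrees(math.acos(min(cos_line, 1.0)))

    plus_id, minus_id = divide_cell(rounded, 1, cv, plus_id=2)
    n_cv_plus, n_cv_minus = pt.partition_particles(
        pt.ParticleSet(res["yellow_positions"], color=pt.YELLOW),
        rounded, plus_id=plus_id, minus_id=minus_id,
    )
    # orient daughters along the original long axis: the (+)-side daughter
    # is the one whose centroid projects further onto a_long
    d_plus = rounded.centroid(plus_id)
    d_minus = rounded.centroid(minus_id)
    if float(np.dot(d_plus - d_minus, a_long)) >= 0:
        out.n_plus, out.n_minus = n_cv_plus, n_cv_minus
    else:
        out.n_plus, out.n_minus = n_cv_minus, n_cv_plus

    state = initial_conditions(out.n_plus, out.n_minus, n_yellow)
    state = resolve_fate(
        state, config.fate, rng=rng_fate, start_mcs=out.div_mcs
    )
    out.plus_fate = state.fate_plus
    out.resolved = state.resolved
    out.fate_mcs = state.mcs_resolved
    out.flags.extend(state.flags)
    return out


def build_fixtures(targets: Sequence[float] = PAPER_ALONG_TARGETS, **kwargs):
    """Tune one fixture per requested A_long target."""
    return {float(t): tune_to_target(float(t), **kwargs) for t in targets}


def _replicate_seed(base_seed: int, shape_idx: int, rep: int) -> int:
    state = np.random.SeedSequence([base_seed, shape_idx, rep]).generate_state(1)
    return int(state[0]) & 0x7FFFFFFF


def run_division_ensemble(
    config: EnsembleConfig,
    fixtures: dict | None = None,
) -> EnsembleResult:
    """Run the division ensemble over all configured shapes.

    Per-replicate seeds derive deterministically from the base seed, so the
    ensemble is reproducible and resumable; replicate-level failures (no
    division, annihilation) are recorded, not fatal.
    """
    if fixtures is None:
        fixtures = build_fixtures(config.a_long_targets)
    rows = []
    for shape_idx, target in enumerate(config.a_long_targets):
        fx = fixtures[float(target)]
        for rep in range(config.replicates):
            seed = _replicate_seed(config.base_seed, shape_idx, rep)
            r = run_single_division(fx, config, seed)
            rows.append(
                {
                    "a_long_target": float(target),
                    "a_long_measured": fx.a_long,
                    "replicate": rep,
                    "seed": seed,
                    "divided": r.divided,
                    "div_mcs": r.div_mcs,
                    "n_yellow": r.n_yellow,
                    "n_blue": r.n_blue,
                    "n_plus": r.n_plus,
                    "n_minus": r.n_minus,
                    "angle_cv_along": r.angle_cv_along,
                    "plus_fate": r.plus_fate,
                    "resolved": r.resolved,
                    "flags": ";".join(r.flags),
                }
            )
    table = pd.DataFrame(rows)
    summary = summarize_ensemble(table)
    return EnsembleResult(table=table, summary=summary, config=config)


def summarize_ensemble(table: pd.DataFrame) -> pd.DataFrame:
    """Per-shape fate counts, bias and chi-squared test against 50:50."""
    out = []
    for target, grp in table.groupby("a_long_target"):
        resolved = grp[grp["resolved"] & grp["divided"]]
        n_v2a = int((resolved["plus_fate"] == "V2a").sum())
        n_v2b = int((resolved["plus_fate"] == "V2b").sum())
        n_res = n_v2a + n_v2b
        if n_res > 0:
            chi2, p = chi_square_gof(
                (n_v2a, n_v2b), (n_res / 2.0, n_res / 2.0), df=1
            )
            bias = n_v2a / n_res
        else:
            chi2, p, bias = float("nan"), float("nan"), float("nan")
        out.append(
            {
                "a_long_target": target,
                "replicates": len(grp),
                "divided": int(grp["divided"].sum()),
                "unresolved": int(len(grp) - n_res),
                "plus_v2a": n_v2a,
                "plus_v2b": n_v2b,
                "bias_plus_v2a": bias,
                "chi2": chi2,
                "p_value": p,
                "mean_div_mcs": float(grp.loc[grp["divided"], "div_mcs"].mean()),
                "median_angle": float(
                    grp.loc[grp["divided"], "angle_cv_along"].median()
                ),
            }
        )
    return pd.DataFrame(out).sort_values("a_long_target").reset_index(drop=True)


def chi_square_gof(
    observed: Sequence[float],
    expected: Sequence[float],
    df: int | None = None,
) -> tuple[float, float]:
    """Chi-squared goodness of fit: chi2 = sum (O_i - E_i)^2 / E_i.

    ``df`` defaults to ``len(observed) - 1`` (1 for the two-fate test, 2 for
    the three-bin division-orientation test).  The p-value is the upper tail
    of the chi-squared distribution.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    if abs(observed.sum() - expected.sum()) > 1e-6 * max(expected.sum(), 1.0):
        raise ValueError("observed and expected totals differ")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    if df is None:
        df = len(observed) - 1
    return chi2, float(stats.chi2.sf(chi2, df))


def long_axis_rule_stats(angles_deg: Sequence[float]) -> dict:
    """Distribution summary of division-axis deviations from the long axis."""
    angles = np.asarray(
        [a for a in angles_deg if np.isfinite(a)], dtype=float
    )
    if len(angles) == 0:
        raise ValueError("no resolved replicates")
    return {
        "n": int(len(angles)),
        "median_deg": float(np.median(angles)),
        "frac_below_30": float(np.mean(angles < 30.0)),
        "frac_below_45": float(np.mean(angles < 45.0)),
    }


DELTA_DYNAMICS_VARIANTS = ("uniform_init", "step_0", "step_4", "ratio_0.0025", "ratio_0.25")


def sweep_delta_dynamics(
    config: EnsembleConfig,
    fixtures: dict | None = None,
    variants: Sequence[str] = DELTA_DYNAMICS_VARIANTS,
    asymmetric_targets: Sequence[float] = (0.052, 0.063, 0.092),
) -> pd.DataFrame:
    """Run the Delta-dynamics perturbations on the asymmetric shapes.

    Variants: ``uniform_init`` (no initial polarization), ``step_0`` /
    ``step_4`` (frozen / fast yellow diffusion), and ``ratio_0.0025`` /
    ``ratio_0.25`` (concentration-to-diffusion ratio via concentrations
    5.0e-3 and 0.50 at step 2).  Returns the concatenated per-shape
    summaries with a ``variant`` column.
    """
    base = replace(config, a_long_targets=tuple(asymmetric_targets))
    if fixtures is None:
        fixtures = build_fixtures(base.a_long_targets)
    mods = {
        "uniform_init": {"init_mode_yellow": "uniform"},
        "step_0": {"step_yellow": 0.0},
        "step_4": {"step_yellow": 4.0},
        "ratio_0.0025": {"conc_yellow": 5.0e-3, "step_yellow": 2.0},
        "ratio_0.25": {"conc_yellow": 0.50, "step_yellow": 2.0},
    }
    frames = []
    for name in variants:
        if name not in mods:
            raise ValueError(f"unknown variant {name!r}")
        cfg = replace(base, **mods[name])
        result = run_division_ensemble(cfg, fixtures)
        summ = result.summary.copy()
        summ.insert(0, "variant", name)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1))


def calibrate_units(
    real_division_minutes: float = 21.0,
    sim_division_mcs: float = 215.0,
    lattice_um: float = 0.5,
    step_lattice_lengths: float = 2.0,
) -> tuple[float, float]:
    """Physical calibration of the simulation units.

    Matching the mean division times (21 min real, 215 mcs simulated) gives
    the seconds per mcs, reported to the nearest second (21 x 60 / 215 =
    5.86 ~ 6 s); the particle step then converts to a diffusion coefficient
    through the two-dimensional surface-diffusion relation MSD = 4 D t with
    MSD = (step x lattice)^2 per mcs, using the rounded time base, reported
    at two significant figures in cm^2/s (step 2 -> 4.2e-10, step 1 ->
    1.0e-10 at the defaults).
    """
    if min(real_division_minutes, sim_division_mcs, lattice_um) <= 0:
        raise ValueError("inputs must be positive")
    if step_lattice_lengths <= 0:
        raise ValueError("step must be positive")
    seconds_per_mcs = round(real_division_minutes * 60.0 / sim_division_mcs)
    step_cm = step_lattice_lengths * lattice_um * 1e-4
    diffusion = step_cm**2 / (4.0 * seconds_per_mcs)
    return float(seconds_per_mcs), _round_sig(diffusion)


def fit_mode(
    config: EnsembleConfig,
    grid: Sequence[tuple[float, float]],
    target_profile: Sequence[float],
    fixtures: dict | None = None,
    replicates: int = 12,
) -> dict:
    """Rank (concentration, step) candidates against a target bias profile.

    Runs ``replicates`` divisions per shape per candidate and scores each
    candidate by the summed squared difference between its per-shape
    (+)-side V2a bias profile and the user-supplied target profile (the
    experimentally observed biases are read off a figure, so they are an
    input here, not a constant).  Returns the ranked report and the
    selected pair.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty candidate grid")
    target_profile = np.asarray(target_profile, dtype=float)
    if len(target_profile) != len(config.a_long_targets):
        raise ValueError("target profile length must match the shape list")
    if fixtures is None:
        fixtures = build_fixtures(config.a_long_targets)
    report = []
    for conc, step in grid:
        cfg = replace(
            config, conc_yellow=conc, step_yellow=step, replicates=replicates
        )
        result = run_division_ensemble(cfg, fixtures)
        bias = result.summary["bias_plus_v2a"].to_numpy()
        score = float(np.nansum((bias - target_profile) ** 2))
        report.append(
            {
                "conc": conc,
                "step": step,
                "bias_profile": bias.tolist(),
                "score": score,
                "n_records": int(len(result.table)),
            }
        )
    report.sort(key=lambda r: r["score"])
    return {"selected": (report[0]["conc"], report[0]["step"]), "ranking": report}
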