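"""Synthetic-data generators with the statistical structure the pipeline assumes.

Three simulators mirror the three experimental arms of the study design:

* :func:`simulate_apms` — a 3-group (surface-labeled at 4 C, endosome-
  containing after a 37 C chase, unlabeled control) x 4-replicate AP-MS
  intensity matrix: log-normal background binders, planted interactors with
  a specified log2 enrichment over control, replicate-level noise, and
  intensity-dependent (missing-not-at-random) dropout following a logistic
  detection curve.
* :func:`simulate_frap` — photobleaching recovery traces
  F(t) = b + Mf * (1 - b) * (1 - exp(-t / tau)) with pre/bleach/post phases.
* :func:`simulate_assays` — paired-condition capture-ELISA plates and
  transwell tracer timecourses.

Scenario parameters are plain dataclasses, serializable to/from YAML.  The
:data:`SCENARIOS` registry ships paired-condition scenarios whose planted
effect sizes equal the published percent changes this package's estimators
are validated against.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .assays import BLEACH, POST, PRE, ElisaPlate, FrapTrace, PermeabilityTimecourse
from .matrix import CONTROL, ENDOSOMAL, SURFACE, IntensityMatrix

__all__ = [
    "ApmsScenario",
    "FrapScenario",
    "AssayScenario",
    "simulate_apms",
    "simulate_frap",
    "simulate_assays",
    "simulate_annotations",
    "simulate_background_frequencies",
    "simulate_categories",
    "frap_traces_to_frame",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "SCENARIOS",
    "paired_scenarios",
]


def _check_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            if not math.isfinite(v):
                raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v}")


# ---------------------------------------------------------------------------
# AP-MS


@dataclass(frozen=True)
class ApmsScenario:
    """Parameters of one synthetic AP-MS experiment.

    Background binders stick to the beads in every channel, so they appear
    at full intensity in the unlabeled control; planted interactors are
    enriched by ``planted_log2fc`` in their compartment(s) and appear in the
    control at their unenriched base level.  Each cell drops out
    independently with probability 1 - logistic(slope * (x - midpoint)) in
    log2 intensity — the left-censoring that downshifted-normal imputation
    models.  ``dropout_midpoint=None`` disables dropout.  The default
    midpoint/slope leave roughly 15% of control-channel cells missing.
    """

    n_background: int = 2000
    n_planted_surface: int = 28
    n_planted_endosomal: int = 53
    n_planted_shared: int = 33
    planted_log2fc: float = 2.0
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.3
    dropout_midpoint: float | None = 22.2
    dropout_slope: float = 1.0
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self)
        for name in ("n_background", "n_planted_surface", "n_planted_endosomal",
                     "n_planted_shared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.base_log2_sd <= 0:
            raise ValueError("base_log2_sd must be > 0")


def _detect_probability(x: np.ndarray, scenario: ApmsScenario) -> np.ndarray:
    if scenario.dropout_midpoint is None:
        return np.ones_like(x)
    z = scenario.dropout_slope * (x - scenario.dropout_midpoint)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_apms(scenario: ApmsScenario) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Simulate a linear-scale intensity matrix and the planted-truth table.

    Returns the matrix (groups surface/endosomal/control x n_replicates,
    NaN for dropped-out cells) and a truth table with one row per planted
    protein and boolean ``surface`` / ``endosomal`` columns.  One RNG stream
    is spawned per protein from the scenario seed, so enlarging the scenario
    never reshuffles the proteins already present.
    """
    groups = (SURFACE, ENDOSOMAL, CONTROL)
    protein_specs: list[tuple[str, bool, bool]] = []
    protein_specs += [(f"BG{i:05d}", False, False) for i in range(scenario.n_background)]
    protein_specs += [(f"SURF{i:04d}", True, False) for i in range(scenario.n_planted_surface)]
    protein_specs += [(f"ENDO{i:04d}", False, True) for i in range(scenario.n_planted_endosomal)]
    protein_specs += [(f"SHRD{i:04d}", True, True) for i in range(scenario.n_planted_shared)]

    n_rep = scenario.n_replicates
    columns = [f"{g}_{r + 1}" for g in groups for r in range(n_rep)]
    values = np.empty((len(protein_specs), len(columns)))

    streams = np.random.SeedSequence(scenario.seed).spawn(len(protein_specs))
    for row, ((pid, in_surface, in_endosomal), ss) in enumerate(zip(protein_specs, streams)):
        rng = np.random.default_rng(ss)
        base = rng.normal(scenario.base_log2_mean, scenario.base_log2_sd)
        enriched = {SURFACE: in_surface, ENDOSOMAL: in_endosomal, CONTROL: False}
        col = 0
        for g in groups:
            mean = base + (scenario.planted_log2fc if enriched[g] else 0.0)
            x = mean + rng.normal(0.0, scenario.noise_sd, size=n_rep)
            detected = rng.random(n_rep) < _detect_probability(x, scenario)
            values[row, col : col + n_rep] = np.where(detected, 2.0**x, np.nan)
            col += n_rep

    index = pd.Index([p[0] for p in protein_specs], name="protein_id")
    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=index, columns=columns), scale="linear"
    )
    truth = pd.DataFrame(
        [(pid, s, e) for pid, s, e in protein_specs if s or e],
        columns=["protein_id", "surface", "endosomal"],
    )
    return matrix, truth


def simulate_annotations(
    matrix_ids,
    truth: pd.DataFrame,
    *,
    seed: int = 0,
    frac_planted_transmembrane: float = 0.3,
    frac_planted_endosome_located: float = 0.25,
) -> pd.DataFrame:
    """Synthetic UniProt-style annotation table for a simulated matrix.

    Planted interactors receive transmembrane topologies and membrane/
    endosome locations at the given rates; background proteins get generic
    cytoplasmic annotations with a small contamination of membrane terms.
    Returns a TSV-ready frame (protein_id, topology, locations '|'-joined).
    """
    rng = np.random.default_rng(seed)
    planted = set(truth["protein_id"])
    topo_terms = [
        "Single-pass type I membrane protein",
        "Single-pass type II membrane protein",
        "Multi-pass membrane protein",
    ]
    membrane_locs = ["Cell membrane", "Cell Junction", "Focal adhesion", "Membrane"]
    endo_locs = ["Early endosome", "Late endosome", "Lysosome", "Cytoplasmic vesicle"]
    other_locs = ["Cytoplasm", "Nucleus", "Mitochondrion", "Cytosol"]
    rows = []
    for pid in matrix_ids:
        is_planted = pid in planted
        tm = rng.random() < (frac_planted_transmembrane if is_planted else 0.05)
        endo = rng.random() < (frac_planted_endosome_located if is_planted else 0.05)
        topology = str(rng.choice(topo_terms)) if tm else "Peripheral membrane protein"
        locs = set()
        if tm:
            locs.update(rng.choice(membrane_locs, size=rng.integers(1, 3), replace=False))
        if endo:
            locs.add(str(rng.choice(endo_locs)))
        if not locs:
            locs.add(str(rng.choice(other_locs)))
        rows.append((pid, topology, "|".join(sorted(locs))))
    return pd.DataFrame(rows, columns=["protein_id", "topology", "locations"])


def simulate_background_frequencies(
    matrix_ids, *, seed: int = 0, frac_frequent: float = 0.05
) -> pd.Series:
    """Synthetic contaminant-repository frequencies: a small frequent-flyer tail."""
    rng = np.random.default_rng(seed)
    ids = list(matrix_ids)
    freq = rng.beta(0.5, 8.0, size=len(ids))  # mostly rare
    frequent = rng.random(len(ids)) < frac_frequent
    freq[frequent] = rng.uniform(0.5, 1.0, size=int(frequent.sum()))
    return pd.Series(freq, index=pd.Index(ids, name="protein_id"), name="frequency")


def simulate_categories(
    matrix_ids, *, seed: int = 0, n_categories: int = 20, size_range: tuple[int, int] = (10, 60)
) -> dict[str, set[str]]:
    """Random GMT-like category memberships over the matrix proteins."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(list(matrix_ids))
    cats: dict[str, set[str]] = {}
    for i in range(n_categories):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(ids))
        cats[f"CAT{i:03d}"] = set(rng.choice(ids, size=size, replace=False))
    return cats


# ---------------------------------------------------------------------------
# FRAP


@dataclass(frozen=True)
class FrapScenario:
    """Parameters of a synthetic FRAP experiment for one condition.

    Each cell's recovery follows F(t) = b + Mf * (1 - b) * (1 - exp(-t/tau))
    on post-bleach frames, with pre-bleach fluorescence 1.0.  ``cell_sd``
    adds biological between-cell spread of the mobile fraction (truncated to
    [0, 1]); ``noise_sd`` is additive per-frame measurement noise.
    """

    mobile_fraction: float = 0.7
    tau_s: float = 10.0
    bleach_floor: float = 0.25
    n_pre: int = 2
    n_bleach: int = 2
    n_post: int = 50
    frame_interval_s: float = 1.4
    noise_sd: float = 0.02
    cell_sd: float = 0.0
    n_cells: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self)
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not self.tau_s > 0:
            raise ValueError("tau_s must be > 0")
        if not 0.0 <= self.bleach_floor < 1.0:
            raise ValueError("bleach_floor must lie in [0, 1)")
        if self.n_post < 2:
            raise ValueError("n_post must be >= 2 (mobile fraction undefined otherwise)")
        if self.noise_sd < 0 or self.cell_sd < 0:
            raise ValueError("noise_sd and cell_sd must be >= 0")


def simulate_frap(scenario: FrapScenario, *, condition: str = "cond") -> list[FrapTrace]:
    """Simulate ``n_cells`` FRAP traces for one condition."""
    dt = scenario.frame_interval_s
    b = scenario.bleach_floor
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.n_cells)
    traces = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        mf = scenario.mobile_fraction
        if scenario.cell_sd > 0:
            mf = float(np.clip(rng.normal(mf, scenario.cell_sd), 0.0, 1.0))
        n_total = scenario.n_pre + scenario.n_bleach + scenario.n_post
        time_s = np.arange(n_total) * dt
        phase = np.array(
            [PRE] * scenario.n_pre + [BLEACH] * scenario.n_bleach + [POST] * scenario.n_post
        )
        t_post = np.arange(scenario.n_post) * dt
        recovery = b + mf * (1.0 - b) * (1.0 - np.exp(-t_post / scenario.tau_s))
        intensity = np.concatenate(
            [np.full(scenario.n_pre, 1.0), np.full(scenario.n_bleach, b), recovery]
        )
        if scenario.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, scenario.noise_sd, size=n_total)
        traces.append(
            FrapTrace(cell_id=f"{condition}_{i:03d}", time_s=time_s, intensity=intensity,
                      phase=phase)
        )
    return traces


def frap_traces_to_frame(traces: list[FrapTrace]) -> pd.DataFrame:
    """Long-format export: cell_id, frame, time_s, intensity, phase."""
    rows = []
    for tr in traces:
        for frame, (t, y, ph) in enumerate(zip(tr.time_s, tr.intensity, tr.phase)):
            rows.append((tr.cell_id, frame, float(t), float(y), str(ph)))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "time_s", "intensity", "phase"])


# ---------------------------------------------------------------------------
# ELISA + permeability


@dataclass(frozen=True)
class AssayScenario:
    """Parameters of paired internalization-ELISA and permeability assays.

    ELISA wells: internalized OD = surface_signal * internalized_fraction +
    background_od; total OD = surface_signal + background_od; background
    wells read background_od.  Permeability: the basal tracer amount grows
    as apical_input * flux_rate * t.  ``noise_cv`` applies multiplicative
    Gaussian noise to every readout.
    """

    internalized_fraction_ctrl: float = 0.3
    internalized_fraction_treat: float = 0.3
    surface_signal: float = 1.2
    background_od: float = 0.05
    flux_rate_ctrl: float = 0.04
    flux_rate_treat: float = 0.04
    apical_input: float = 100.0
    sample_times_h: tuple[float, ...] = (2.0, 4.0, 6.0)
    n_replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self)
        for name in ("internalized_fraction_ctrl", "internalized_fraction_treat"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        times = np.asarray(self.sample_times_h, dtype=float)
        if times.size < 2 or not (np.diff(times) > 0).all():
            raise ValueError("sample_times_h must be strictly increasing with >= 2 points")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _noised(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    vals = np.full(size, mean, dtype=float)
    if cv > 0:
        vals = vals * (1.0 + rng.normal(0.0, cv, size=size))
    return np.clip(vals, 0.0, None)


def simulate_assays(
    scenario: AssayScenario,
) -> tuple[tuple[ElisaPlate, ElisaPlate], tuple[PermeabilityTimecourse, PermeabilityTimecourse]]:
    """Simulate (control, treated) ELISA plates and permeability timecourses."""
    rng = np.random.default_rng(scenario.seed)
    plates = []
    for cond, frac in (
        ("ctrl", scenario.internalized_fraction_ctrl),
        ("treat", scenario.internalized_fraction_treat),
    ):
        plates.append(
            ElisaPlate(
                condition=cond,
                internalized=_noised(
                    rng,
                    scenario.surface_signal * frac + scenario.background_od,
                    scenario.noise_cv,
                    scenario.n_replicates,
                ),
                total=_noised(
                    rng,
                    scenario.surface_signal + scenario.background_od,
                    scenario.noise_cv,
                    scenario.n_replicates,
                ),
                background=_noised(
                    rng, scenario.background_od, scenario.noise_cv, scenario.n_replicates
                ),
            )
        )
    timecourses = []
    times = np.asarray(scenario.sample_times_h, dtype=float)
    for cond, rate in (("ctrl", scenario.flux_rate_ctrl), ("treat", scenario.flux_rate_treat)):
        signal = np.array(
            [_noised(rng, scenario.apical_input * rate * t, scenario.noise_cv, 1)[0]
             for t in times]
        )
        timecourses.append(
            PermeabilityTimecourse(
                condition=cond,
                time_h=times,
                basal_signal=signal,
                apical_input=scenario.apical_input,
            )
        )
    return (plates[0], plates[1]), (timecourses[0], timecourses[1])


# ---------------------------------------------------------------------------
# YAML round-trip

_SCENARIO_TYPES = {cls.__name__: cls for cls in (ApmsScenario, FrapScenario, AssayScenario)}


def scenario_to_yaml(scenario, path: str | Path) -> None:
    payload = {"type": type(scenario).__name__, "params": asdict(scenario)}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def scenario_from_yaml(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    cls = _SCENARIO_TYPES[payload["type"]]
    params = dict(payload["params"])
    if "sample_times_h" in params:
        params["sample_times_h"] = tuple(params["sample_times_h"])
    return cls(**params)


# ---------------------------------------------------------------------------
# shipped paired-condition scenarios
#
# Effect sizes are the published percent changes the estimators are
# validated against: NRP1 knockdown reduces the VE-cadherin FRAP mobile
# fraction by 37% and VE-cadherin internalization by 26%; mini-WARS
# overexpression reduces NRP1 endocytosis by 19% and VE-cadherin
# endocytosis by 18%.


def _frap_vecad_nrp1_kd(seed: int) -> tuple[FrapScenario, FrapScenario]:
    ctrl = FrapScenario(
        mobile_fraction=0.75, tau_s=10.0, bleach_floor=0.25, noise_sd=0.03,
        cell_sd=0.06, n_cells=24, seed=seed,
    )
    treat = replace(ctrl, mobile_fraction=0.75 * (1.0 - 0.37), seed=seed + 1)
    return ctrl, treat


def _elisa_pair(frac_ctrl: float, reduction: float, seed: int) -> AssayScenario:
    return AssayScenario(
        internalized_fraction_ctrl=frac_ctrl,
        internalized_fraction_treat=frac_ctrl * (1.0 - reduction),
        seed=seed,
    )


SCENARIOS: dict[str, Callable[[int], object]] = {
    # VE-cadherin-mCherry FRAP at adherens junctions, siNRP1 vs siCtrl
    "frap_vecad_nrp1_kd": _frap_vecad_nrp1_kd,
    # surface-biotinylation VE-cadherin internalization, siNRP1 vs siCtrl
    "internalization_vecad_nrp1_kd": lambda seed: _elisa_pair(0.30, 0.26, seed),
    # NRP1 endocytosis under mini-WARS overexpression vs control
    "endocytosis_nrp1_miniwars": lambda seed: _elisa_pair(0.25, 0.19, seed),
    # VE-cadherin endocytosis under mini-WARS overexpression vs control
    "endocytosis_vecad_miniwars": lambda seed: _elisa_pair(0.25, 0.18, seed),
}


def paired_scenarios(name: str, seed: int = 0):
    """Instantiate a shipped paired-condition scenario by registry name."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    return SCENARIOS[name](seed)
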