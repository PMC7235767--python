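"""Study-shaped synthetic data: gLV communities, noisy count tables on the
4-condition x 4-day x 3-replicate sampling design, and feeding-schedule
fixtures for the chemistry stage."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .amplicon_profiles import AbundanceTable
from .glv_core import DEFAULT_FLOOR, BlowupError, GLVModel, Trajectory, simulate

CONDITIONS = ("control", "nalidixic", "GABA", "phosphate")


class GenerationError(RuntimeError):
    """Community generation failed persistence checks."""


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the emulated experiment."""

    conditions: tuple[str, ...] = CONDITIONS
    sampling_days: tuple[int, ...] = (0, 56, 70, 77)
    replicates: int = 3
    depth: int = 50_000
    n_taxa: int = 24

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.depth < 1 or self.n_taxa < 1:
            raise ValueError("replicates, depth and n_taxa must be >= 1")
        if any(b <= a for a, b in zip(self.sampling_days, self.sampling_days[1:])):
            raise ValueError("sampling days must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * len(self.sampling_days) * self.replicates


@dataclass(frozen=True)
class PerturbationSpec:
    """Step change applied to a condition's model from ``start_day`` onward.

    ``r_shift`` is added to every growth rate; ``a_offdiag_shift`` is added
    to every off-diagonal interaction coefficient (negative values push the
    community toward competition).
    """

    r_shift: float = 0.0
    a_offdiag_shift: float = 0.0
    start_day: float = 42.0

    def apply(self, model: GLVModel) -> GLVModel:
        A = model.A.copy()
        off = ~np.eye(model.n, dtype=bool)
        A[off] += self.a_offdiag_shift
        return GLVModel(taxa=list(model.taxa), r=model.r + self.r_shift, A=A)


def default_perturbations(scale: float = 0.02) -> dict[str, PerturbationSpec]:
    """Competitive off-diagonal shifts of increasing strength for the stressors."""
    return {
        "nalidixic": PerturbationSpec(a_offdiag_shift=-1.0 * scale, r_shift=-0.01),
        "GABA": PerturbationSpec(a_offdiag_shift=-1.5 * scale, r_shift=-0.02),
        "phosphate": PerturbationSpec(a_offdiag_shift=-0.5 * scale, r_shift=-0.005),
    }


def interior_equilibrium(model: GLVModel) -> np.ndarray | None:
    """Solve A x = -r; return the fixed point if it is strictly positive."""
    try:
        x = np.linalg.solve(model.A, -model.r)
    except np.linalg.LinAlgError:
        return None
    return x if np.all(x > 0) else None


def sample_model(
    n_taxa: int,
    sparsity: float = 0.3,
    interaction_scale: float = 0.5,
    seed: int | None = None,
    max_retries: int = 12,
    horizon: float = 77.0,
    floor: float = DEFAULT_FLOOR,
) -> GLVModel:
    """Draw a random persistent gLV community.

    Self-interactions are negative (self-limitation); off-diagonals are zero
    with probability ``sparsity`` and otherwise signed half-normal with the
    given scale (in units of the diagonal). Growth rates are set so a chosen
    positive composition is an interior equilibrium; off-diagonals are
    halved until the simulated community persists (all abundances above the
    floor, no blow-up) over the design horizon.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0 <= sparsity <= 1:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = [f"OTU_{i + 1:03d}" for i in range(n_taxa)]
    diag = -rng.uniform(1.0, 2.0, n_taxa)
    magnitudes = np.abs(rng.standard_normal((n_taxa, n_taxa))) * interaction_scale
    signs = rng.choice([-1.0, 1.0], size=(n_taxa, n_taxa))
    keep = rng.random((n_taxa, n_taxa)) >= sparsity
    off = magnitudes * signs * keep
    np.fill_diagonal(off, 0.0)
    # equilibrium composition on the simplex scale of relative abundances
    xstar = rng.dirichlet(np.full(n_taxa, 5.0))
    x0 = xstar * rng.uniform(0.6, 1.5, n_taxa)
    for _ in range(max_retries):
        A = off * np.abs(diag)[:, None]
        np.fill_diagonal(A, diag / np.mean(xstar))
        r = -A @ xstar
        if np.all(r > 0):
            model = GLVModel(taxa=taxa, r=r, A=A)
            try:
                traj = simulate(model, x0, np.linspace(0.0, horizon, 40), floor=floor)
            except (BlowupError, RuntimeError):
                traj = None
            if traj is not None and np.all(traj.X > floor):
                return model
        off *= 0.5
    raise GenerationError(
        f"no persistent community after {max_retries} retries; "
        f"try a smaller interaction_scale than {interaction_scale}"
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _simulate_condition(
    model: GLVModel,
    x0: np.ndarray,
    days: Sequence[float],
    perturbation: PerturbationSpec | None,
) -> dict[float, np.ndarray]:
    """State at each sampling day, with an optional step perturbation."""
    days = [float(d) for d in days]
    last = max(days)
    if perturbation is None or perturbation.start_day >= last:
        times = sorted({0.0, *days})
        traj = simulate(model, x0, np.asarray(times))
        return {d: traj.X[times.index(d)] for d in days}
    t_switch = float(perturbation.start_day)
    pre_days = [d for d in days if d <= t_switch]
    times1 = sorted({0.0, *pre_days, t_switch})
    traj1 = simulate(model, x0, np.asarray(times1))
    state = {d: traj1.X[times1.index(d)] for d in pre_days}
    x_switch = traj1.X[-1]
    post_days = [d for d in days if d > t_switch]
    if post_days:
        times2 = sorted({t_switch, *post_days})
        traj2 = simulate(perturbation.apply(model), x_switch, np.asarray(times2))
        state.update({d: traj2.X[times2.index(d)] for d in post_days})
    return state


def generate_counts(
    model: GLVModel,
    design: StudyDesign,
    perturbations: Mapping[str, PerturbationSpec] | None = None,
    x0: np.ndarray | None = None,
    noise_cv: float = 0.05,
    seed: int | None = None,
) -> tuple[AbundanceTable, dict]:
    """Noisy multinomial count table on the study design, plus ground truth.

    Each condition's trajectory is simulated (with its perturbation, if
    any), evaluated at the sampling days, multiplied per replicate by
    lognormal noise of coefficient of variation ``noise_cv``, closed to
    proportions and sampled as multinomial counts at the design depth.
    """
    perturbations = dict(perturbations or {})
    rng = np.random.default_rng(seed)
    if x0 is None:
        eq = interior_equilibrium(model)
        x0 = eq if eq is not None else np.full(model.n, 1.0 / model.n)
        x0 = x0 * np.linspace(0.8, 1.25, model.n)  # off-equilibrium start
    rows, meta_rows, truth_props = [], [], {}
    for cond in design.conditions:
        states = _simulate_condition(
            model, np.asarray(x0, float), design.sampling_days, perturbations.get(cond)
        )
        for day in design.sampling_days:
            x = states[float(day)]
            true_p = x / x.sum()
            for rep in range(1, design.replicates + 1):
                sid = f"{cond}_d{day}_r{rep}"
                noisy = x * _lognormal_factors(rng, noise_cv, model.n)
                p = noisy / noisy.sum()
                counts = rng.multinomial(design.depth, p)
                rows.append(pd.Series(counts, index=model.taxa, name=sid))
                meta_rows.append(
                    {"sample_id": sid, "condition": cond, "day": day, "replicate": rep}
                )
                truth_props[sid] = true_p.tolist()
    counts_df = pd.DataFrame(rows).astype(int)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    lineages = {t: _synthetic_lineage(i) for i, t in enumerate(model.taxa)}
    table = AbundanceTable(counts=counts_df, lineages=lineages, metadata=metadata)
    truth = {
        "taxa": model.taxa,
        "r": model.r.tolist(),
        "A": model.A.tolist(),
        "perturbations": {
            c: {
                "r_shift": p.r_shift,
                "a_offdiag_shift": p.a_offdiag_shift,
                "start_day": p.start_day,
            }
            for c, p in perturbations.items()
        },
        "true_proportions": truth_props,
        "noise_cv": noise_cv,
        "depth": design.depth,
    }
    return table, truth


_PHYLA = ("Bacteroidetes", "Firmicutes", "Chloroflexi", "Proteobacteria")


def _synthetic_lineage(i: int) -> tuple[str, ...]:
    phylum = _PHYLA[i % len(_PHYLA)]
    return ("Bacteria", phylum, f"Class{i % 6 + 1}", f"Order{i % 8 + 1}",
            f"Family{i % 10 + 1}", f"Genus{i + 1:03d}")


# ---------------------------------------------------------------------------
# Feeding-schedule fixture

#: Weekly glucose dose (g/L per feeding): 1 g/L for 3 weeks, then 3 g/L.
_GLUCOSE_BY_WEEK = (1.0,) * 3 + (3.0,) * 8
#: Escalating weekly stressor doses for weeks 7-11 (g/L); organic doses sum
#: to 21.11, phosphate doses to 20.5.
_ORGANIC_DOSES = (0.01, 0.1, 1.0, 10.0, 10.0)
_PHOSPHATE_DOSES = (0.5, 5.0, 5.0, 5.0, 5.0)
_FEEDING_OFFSETS = (0, 2, 4)


def feeding_schedule() -> dict:
    """Eleven-week schedule mirroring the emulated feeding regime."""
    conditions: dict[str, list[dict]] = {}
    for cond in CONDITIONS:
        events = []
        for week in range(11):
            glucose = _GLUCOSE_BY_WEEK[week]
            stress_week = week - 6  # stressors start in week 7
            for i, offset in enumerate(_FEEDING_OFFSETS):
                ev = {
                    "day": week * 7 + offset,
                    "substrate_load": glucose,
                    "stressor_load": 0.0,
                    "stressor_is_organic": cond in ("nalidixic", "GABA"),
                }
                if i == 0 and 0 <= stress_week < 5 and cond != "control":
                    doses = (
                        _PHOSPHATE_DOSES if cond == "phosphate" else _ORGANIC_DOSES
                    )
                    ev["stressor_load"] = doses[stress_week]
                events.append(ev)
        conditions[cond] = events
    return {
        "reactor": {"working_volume": 3.0, "exchange_volume": 0.15, "feedings_per_week": 3},
        "conditions": conditions,
    }


def generate_study(
    out_dir: str | Path,
    design: StudyDesign | None = None,
    perturbations: Mapping[str, PerturbationSpec] | None = None,
    seed: int | None = None,
    noise_cv: float = 0.05,
    interaction_scale: float = 0.5,
    sparsity: float = 0.3,
) -> dict[str, Path]:
    """Write a complete synthetic study fixture directory.

    Outputs ``counts.tsv``, ``metadata.tsv``, ``truth.json`` and
    ``schedule.yaml`` under ``out_dir``; returns the path map.
    """
    design = design or StudyDesign()
    if perturbations is None:
        perturbations = default_perturbations()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = sample_model(
        design.n_taxa, sparsity=sparsity, interaction_scale=interaction_scale, seed=seed
    )
    table, truth = generate_counts(
        model, design, perturbations=perturbations, noise_cv=noise_cv, seed=seed
    )
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
        "schedule": out / "schedule.yaml",
    }
    table.to_tsv(paths["counts"], paths["metadata"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    with open(paths["schedule"], "w") as fh:
        yaml.safe_dump(feeding_schedule(), fh, sort_keys=False)
    return paths
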