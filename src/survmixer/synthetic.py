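"""Synthetic cohorts with known pathway-level survival signal.

The generator emulates the structure the pipeline assumes in real data:

* a gene-set collection (disjoint pathway memberships by default, with an
  optional overlap fraction to mimic KEGG-style sharing);
* per-sample latent pathway *activities* (standard normal) that drive the
  member genes' expression (activity + Gaussian noise, then per-gene
  min-max scaled to [0, 1]);
* exponential survival times whose log-hazard is a linear function of the
  mean activity over a designated subset of *effect pathways*;
* independent uniform right-censoring calibrated to a requested rate.

Because the ground-truth activities and effect pathways are returned, the
generator supports end-to-end recovery tests: a model trained on the
images should separate the survival classes, and the interpretation chain
should point back at the planted pathways.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geneset import PathwayCollection
from .imaging import ExpressionMatrix, minmax_normalize, write_expression
from .labeling import SurvivalRecord


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Study conditions for one generated cohort.

    Defaults describe a mid-sized cohort with a strong two-pathway signal:
    400 samples, 40 pathways of 3-46 genes (the size range of a typical
    curated cancer-pathway collection), expression noise sd 0.3 on unit-
    variance activities, hazard effect 2.0 on the mean effect-pathway
    activity, baseline hazard 0.2/year (median survival ~3.5 years at
    average activity) and 20% censoring.
    """

    n_samples: int = 400
    n_pathways: int = 40
    size_min: int = 3
    size_max: int = 46
    n_background_genes: int = 100
    effect_pathways: tuple[int, ...] = (0, 1)
    effect_size: float = 2.0
    noise_sd: float = 0.3
    censoring_rate: float = 0.2
    baseline_hazard: float = 0.2
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_pathways < 1:
            raise SyntheticError("n_samples and n_pathways must be >= 1")
        if not 1 <= self.size_min <= self.size_max:
            raise SyntheticError(f"invalid pathway size range [{self.size_min}, {self.size_max}]")
        if not all(0 <= i < self.n_pathways for i in self.effect_pathways):
            raise SyntheticError("effect_pathways must index existing pathways")
        if not 0 <= self.censoring_rate < 1:
            raise SyntheticError("censoring_rate must be in [0, 1)")
        if not 0 <= self.overlap_fraction < 1:
            raise SyntheticError("overlap_fraction must be in [0, 1)")
        if self.effect_size < 0 or self.noise_sd < 0 or self.baseline_hazard <= 0:
            raise SyntheticError("effect_size, noise_sd >= 0 and baseline_hazard > 0 required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_pathways"] = list(self.effect_pathways)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "effect_pathways" in d:
            d["effect_pathways"] = tuple(d["effect_pathways"])
        return cls(**d)


def generate_collection(spec: SyntheticSpec) -> PathwayCollection:
    """Deterministically generate named pathways with sizes in the spec range.

    Pathways are gene-disjoint unless ``overlap_fraction`` > 0, in which
    case that fraction of each pathway's genes (after the first) is drawn
    from previously assigned genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6e5e7]))
    sizes = rng.integers(spec.size_min, spec.size_max + 1, size=spec.n_pathways)
    items: list[tuple[str, list[str]]] = []
    counter = 0
    assigned: list[str] = []
    for k, size in enumerate(sizes):
        genes: list[str] = []
        for j in range(int(size)):
            reuse = (
                spec.overlap_fraction > 0
                and j > 0
                and assigned
                and rng.random() < spec.overlap_fraction
            )
            if reuse:
                g = assigned[int(rng.integers(len(assigned)))]
                if g in genes:
                    reuse = False
            if not reuse:
                g = f"G{counter:05d}"
                counter += 1
            genes.append(g)
        assigned.extend(g for g in genes if g not in assigned)
        items.append((f"PW{k:03d}", genes))
    return PathwayCollection.from_lists(items)


def _calibrate_censoring_tmax(times: np.ndarray, rate: float) -> float:
    """Bisect T_max so that C ~ U(0, T_max) censors ≈ ``rate`` of samples.

    P(censored | T=t) = min(t / T_max, 1) for uniform censoring, so the
    expected rate is mean(min(T / T_max, 1)), decreasing in T_max.
    """
    lo, hi = times.max() * 1e-6, times.max() * 1e6

    def expected(tmax: float) -> float:
        return float(np.minimum(times / tmax, 1.0).mean())

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if expected(mid) > rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the generating ground truth."""

    expression: ExpressionMatrix
    records: list[SurvivalRecord]
    activities: np.ndarray  # (n_samples, n_pathways) latent truth
    spec: SyntheticSpec
    censoring_tmax: float | None = None

    def truth(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "effect_pathway_names": [f"PW{i:03d}" for i in self.spec.effect_pathways],
            "censoring_tmax": self.censoring_tmax,
        }


def generate_cohort(spec: SyntheticSpec, collection: PathwayCollection) -> SyntheticCohort:
    """Draw one cohort under ``spec`` using the given (generated) collection.

    Latent activity a_p ~ N(0, 1) per (sample, pathway); member-gene
    expression = a_p + N(0, noise_sd), min-max scaled per gene; survival
    T ~ Exponential(rate = baseline_hazard * exp(effect_size * mean of
    a_p over effect pathways)); uniform censoring hits ≈ censoring_rate.
    """
    if len(collection) != spec.n_pathways:
        raise SyntheticError(
            f"collection has {len(collection)} pathways, spec expects {spec.n_pathways}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xc047]))
    n = spec.n_samples
    activities = rng.standard_normal((n, spec.n_pathways))

    gene_ids: list[str] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for k, p in enumerate(collection):
        for g in p.genes:
            if g in seen:
                continue  # overlapping gene: driven by its first pathway
            seen.add(g)
            gene_ids.append(g)
            columns.append(activities[:, k] + rng.normal(0.0, spec.noise_sd, size=n))
    for b in range(spec.n_background_genes):
        gene_ids.append(f"BG{b:05d}")
        columns.append(rng.standard_normal(n))
    values = np.column_stack(columns)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    expr = minmax_normalize(ExpressionMatrix(sample_ids, gene_ids, values))

    if spec.effect_pathways:
        score = activities[:, list(spec.effect_pathways)].mean(axis=1)
    else:
        score = np.zeros(n)
    hazard = spec.baseline_hazard * np.exp(spec.effect_size * score)
    t_true = rng.exponential(1.0 / hazard)

    tmax = None
    if spec.censoring_rate > 0:
        tmax = _calibrate_censoring_tmax(t_true, spec.censoring_rate)
        c = rng.uniform(0.0, tmax, size=n)
        observed = np.minimum(t_true, c)
        event = (t_true <= c).astype(int)
    else:
        observed = t_true
        event = np.ones(n, dtype=int)

    records = [
        SurvivalRecord(sample_ids[i], float(observed[i]), int(event[i])) for i in range(n)
    ]
    return SyntheticCohort(expr, records, activities, spec, tmax)


def write_dataset(cohort: SyntheticCohort, collection: PathwayCollection, directory: str | Path) -> dict[str, Path]:
    """Emit the TSV/GMT files the real-data readers consume, plus truth JSON."""
    from .geneset import write_gmt
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gmt": directory / "pathways.gmt",
        "expression": directory / "expression.tsv",
        "survival": directory / "survival.tsv",
        "truth": directory / "truth.json",
    }
    write_gmt(collection, paths["gmt"])
    write_expression(cohort.expression, paths["expression"])
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in cohort.records],
            "os_time": [r.os_time for r in cohort.records],
            "os_event": [r.event for r in cohort.records],
        }
    ).to_csv(paths["survival"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(cohort.truth(), indent=1))
    return paths
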