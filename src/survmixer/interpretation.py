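"""Model interpretation: Grad-CAM, rank tests, GSVA and Kaplan-Meier.

The chain mirrors how the trained classifier is interrogated:

1. **Grad-CAM** — for each sample, channel importances are the spatial
   average of d(pre-sigmoid score)/d(feature map) at a chosen layer
   (Z = grid**2 positions); the activation map is the ReLU of the
   importance-weighted channel sum. One grid position = one pathway.
2. **Rank tests** — per pathway, a two-sided Wilcoxon rank-sum test
   compares the activation at its grid slot between the two ground-truth
   label groups; blank slots are excluded; Bonferroni correction over the
   tested pathways yields the *key pathways* (corrected p < 0.05).
3. **GSVA + Kaplan-Meier** — pathway-level expression scores (gene set
   variation analysis) are median-split per key pathway and the two
   groups' survival compared by log-rank, validating that the pathways
   the model attends to actually separate survival.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .geneset import PathwayCollection
from .imaging import ExpressionMatrix, ImageLayout
from .labeling import SurvivalRecord
from .model import SurvConvMixer

# exact rank-sum enumeration is used when both groups are at most this size
# (and the pooled values are tie-free); larger groups use the normal
# approximation with continuity and tie correction
_EXACT_MAX_GROUP = 10


class InterpretationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

@dataclass
class ActivationMaps:
    """Per-sample non-negative grid maps for one target class."""

    maps: np.ndarray  # (n_samples, grid, grid), all >= 0
    target_class: int
    layer: str
    z: int  # number of positions averaged over in the channel importances

    def __post_init__(self) -> None:
        if (self.maps < 0).any():
            raise InterpretationError("activation maps must be non-negative")


def gradcam(
    model: SurvConvMixer,
    images: np.ndarray,
    target_class: int = 1,
    layer: str | None = None,
) -> ActivationMaps:
    """Gradient-weighted class activation maps at a named layer.

    Channel importances: alpha_n = (1/Z) * sum_ij d(y)/d(A^n_ij), where y
    is the pre-sigmoid score and Z the number of positions per map. The
    map is ReLU(sum_n alpha_n * A^n). ``target_class=0`` flips the
    gradient sign (the score of the survival class is -y).
    """
    if layer is None:
        layer = model.stage_names()[-1]
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    features, grads = model.gradient_at(images, layer)
    if target_class == 0:
        grads = -grads
    elif target_class != 1:
        raise InterpretationError(f"target_class must be 0 or 1, got {target_class}")
    z = features.shape[2] * features.shape[3]
    alpha = grads.sum(axis=(2, 3)) / z  # (n, C)
    raw = np.einsum("nc,nchw->nhw", alpha, features)
    return ActivationMaps(np.maximum(raw, 0.0), target_class, layer, z)


def pathway_activations(maps: ActivationMaps, layout: ImageLayout) -> pd.DataFrame:
    """Scalar activation per (sample, pathway): the value at the pathway's slot.

    Blank slots carry no pathway and are excluded by construction.
    """
    grids = maps.maps
    if grids.shape[1:] != (layout.grid_side, layout.grid_side):
        raise InterpretationError(
            f"map grid {grids.shape[1:]} does not match layout grid "
            f"({layout.grid_side}, {layout.grid_side})"
        )
    names = list(layout.pathway_slots)
    rows = np.array([layout.pathway_slots[p][0] for p in names])
    cols = np.array([layout.pathway_slots[p][1] for p in names])
    return pd.DataFrame(grids[:, rows, cols], columns=names)


# ---------------------------------------------------------------------------
# Rank tests with Bonferroni correction
# ---------------------------------------------------------------------------

def rank_sum_p(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 10 values and the pooled
    values are tie-free; otherwise the normal approximation with
    continuity and tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InterpretationError("rank-sum test needs non-empty groups")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= _EXACT_MAX_GROUP and b.size <= _EXACT_MAX_GROUP and tie_free) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def wilcoxon_keypathways(
    activations: pd.DataFrame,
    labels: Sequence[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pathway rank-sum test between label groups, Bonferroni-corrected.

    Returns a frame indexed by pathway with columns raw_p, corrected_p,
    significant (corrected_p < alpha). corrected_p = min(1, raw_p * m)
    with m the number of pathways tested.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(activations):
        raise InterpretationError("labels length does not match activation rows")
    if not ((y == 0).any() and (y == 1).any()):
        raise InterpretationError("both label groups must be non-empty")
    m = activations.shape[1]
    raw = np.array(
        [rank_sum_p(activations.iloc[y == 1, j], activations.iloc[y == 0, j]) for j in range(m)]
    )
    corrected = np.minimum(1.0, raw * m)
    return pd.DataFrame(
        {"raw_p": raw, "corrected_p": corrected, "significant": corrected < alpha},
        index=activations.columns,
    )


# ---------------------------------------------------------------------------
# GSVA pathway scores
# ---------------------------------------------------------------------------

def gsva_scores(
    m: ExpressionMatrix,
    collection: PathwayCollection,
    kcdf: str = "Gaussian",
    seed: int = 0,
) -> pd.DataFrame:
    """Pathways x samples gene set variation analysis scores.

    Rank-based per-sample enrichment of each pathway's member genes
    relative to all genes in the matrix. Member genes absent from the
    matrix are dropped with a warning; a pathway with no matched genes
    gets an all-NaN row and a warning.
    """
    import gseapy

    if len(m.sample_ids) < 3:
        raise InterpretationError("GSVA needs at least 3 samples")
    present = set(m.gene_ids)
    gene_sets: dict[str, list[str]] = {}
    empty: list[str] = []
    for p in collection:
        matched = [g for g in p.genes if g in present]
        missing = len(p.genes) - len(matched)
        if missing:
            warnings.warn(
                f"pathway {p.name!r}: {missing}/{len(p.genes)} member genes absent from the matrix"
            )
        if matched:
            gene_sets[p.name] = matched
        else:
            empty.append(p.name)
    if empty:
        warnings.warn(f"pathways with no matched genes (scores undefined): {empty}")
    if not gene_sets:
        raise InterpretationError("no pathway has any gene present in the matrix")

    expr = m.to_dataframe().T  # genes x samples, as GSVA expects
    res = gseapy.gsva(
        data=expr,
        gene_sets=gene_sets,
        outdir=None,
        kcdf=kcdf,
        min_size=1,
        max_size=100000,
        threads=1,
        seed=seed,
    )
    wide = res.res2d.pivot(index="Term", columns="Name", values="ES").astype(float)
    wide = wide.reindex(index=[p.name for p in collection], columns=m.sample_ids)
    return wide


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank on median-split pathway scores
# ---------------------------------------------------------------------------

def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate as (time, survival) step points."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def km_logrank(
    scores: pd.Series,
    records: list[SurvivalRecord],
) -> dict:
    """Median-split survival comparison for one pathway score.

    ``scores`` is indexed by sample_id. High group: score > median; low
    group: score <= median (ties to low). Returns the group memberships,
    each group's Kaplan-Meier step curve, and the two-group log-rank p.
    """
    from lifelines.statistics import logrank_test

    by_id = {r.sample_id: r for r in records}
    common = [s for s in scores.index if s in by_id]
    if len(common) < 4:
        raise InterpretationError("need at least 4 samples with both a score and survival")
    s = scores.loc[common].astype(float)
    if s.isna().any():
        raise InterpretationError("scores contain NaN")
    median = float(s.median())
    high_ids = [i for i in common if s.loc[i] > median]
    low_ids = [i for i in common if s.loc[i] <= median]
    if len(high_ids) < 2 or len(low_ids) < 2:
        raise InterpretationError(
            f"degenerate median split (high={len(high_ids)}, low={len(low_ids)}); "
            "scores may be constant"
        )
    t_hi = np.array([by_id[i].os_time for i in high_ids])
    e_hi = np.array([by_id[i].event for i in high_ids])
    t_lo = np.array([by_id[i].os_time for i in low_ids])
    e_lo = np.array([by_id[i].event for i in low_ids])
    res = logrank_test(t_hi, t_lo, event_observed_A=e_hi, event_observed_B=e_lo)
    return {
        "median": median,
        "high_ids": high_ids,
        "low_ids": low_ids,
        "high_curve": km_curve(t_hi, e_hi),
        "low_curve": km_curve(t_lo, e_lo),
        "logrank_p": float(res.p_value),
        "logrank_statistic": float(res.test_statistic),
    }


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class KeyPathwayReport:
    """Rank-test table plus GSVA/KM validation of the key pathways."""

    tests: pd.DataFrame  # index pathway; raw_p, corrected_p, significant
    km: dict[str, dict] = field(default_factory=dict)  # pathway -> km_logrank output
    alpha: float = 0.05
    layer: str = ""

    @property
    def key_pathways(self) -> list[str]:
        return list(self.tests.index[self.tests["significant"]])

    def to_frame(self) -> pd.DataFrame:
        df = self.tests.copy()
        df["logrank_p"] = [self.km.get(p, {}).get("logrank_p", np.nan) for p in df.index]
        return df

    def save(self, directory: str | Path, stem: str = "key_pathways") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{stem}.tsv", sep="\t", index_label="pathway")
        payload = {
            "alpha": self.alpha,
            "layer": self.layer,
            "key_pathways": self.key_pathways,
            "tests": {
                p: {
                    "raw_p": float(self.tests.loc[p, "raw_p"]),
                    "corrected_p": float(self.tests.loc[p, "corrected_p"]),
                    "significant": bool(self.tests.loc[p, "significant"]),
                }
                for p in self.tests.index
            },
            "km": {
                p: {
                    "median": d["median"],
                    "logrank_p": d["logrank_p"],
                    "logrank_statistic": d["logrank_statistic"],
                    "n_high": len(d["high_ids"]),
                    "n_low": len(d["low_ids"]),
                }
                for p, d in self.km.items()
            },
        }
        (directory / f"{stem}.json").write_text(json.dumps(payload, indent=1))
        for p, d in self.km.items():
            safe = p.replace("/", "_").replace(" ", "_")
            d["high_curve"].to_csv(directory / f"{stem}.{safe}.high.tsv", sep="\t", index=False)
            d["low_curve"].to_csv(directory / f"{stem}.{safe}.low.tsv", sep="\t", index=False)


def find_key_pathways(
    model: SurvConvMixer,
    images: np.ndarray,
    labels: Sequence[int],
    sample_ids: Sequence[str],
    expression: ExpressionMatrix,
    collection: PathwayCollection,
    records: list[SurvivalRecord],
    alpha: float = 0.05,
    layer: str | None = None,
    gsva_kcdf: str = "Gaussian",
    seed: int = 0,
) -> KeyPathwayReport:
    """Run the whole interpretation chain on a trained model.

    Activation maps are computed for the death class for every sample,
    grouped by ground-truth label for the rank tests; key pathways are
    then validated by GSVA median-split Kaplan-Meier with log-rank.
    """
    maps = gradcam(model, images, target_class=1, layer=layer)
    act = pathway_activations(maps, model.layout)
    tests = wilcoxon_keypathways(act, labels, alpha=alpha)
    report = KeyPathwayReport(tests=tests, alpha=alpha, layer=maps.layer)
    if report.key_pathways:
        scores = gsva_scores(expression, collection, kcdf=gsva_kcdf, seed=seed)
        for p in report.key_pathways:
            row = scores.loc[p]
            if row.isna().all():
                continue
            try:
                report.km[p] = km_logrank(row, records)
            except InterpretationError as exc:
                warnings.warn(f"KM skipped for {p!r}: {exc}")
    return report
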