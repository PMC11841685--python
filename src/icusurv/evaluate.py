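"""Concordance evaluation and the bootstrap model-comparison protocol.

The concordance index (C-index) is the fraction of comparable subject pairs
that the model orders correctly: among pairs where the subject with the
strictly shorter observed time had an observed event, the pair is concordant
when that subject also received the strictly higher risk score (0.5 credit
on risk ties).  Higher risk must predict shorter survival; a random score
gives 0.5 in expectation and a perfect anti-ordering gives 1.  Pairs with
tied observed times, and pairs whose shorter time is censored, are not
comparable.

The experiment protocol bootstraps the whole cohort: each replicate resamples
n subjects with replacement, splits 70/10/20 into train/validation/test,
trains the model (validation drives early stopping for the neural model) and
scores the test C-index.  Replicate seeds are shared across models so
pairwise comparisons (Wilcoxon signed-rank by default) are validly paired.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import findings
from .cox import ConvergenceError, fit_linear_cox
from .encoders import GCNParams, normalize_adjacency, default_concept_graph
from .fusion import (
    FusionConfig,
    encode_modalities,
    risk_forward_batch,
    train_on_arrays,
)
from .synthetic import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "CIndexResult",
    "BootstrapResult",
    "ComparisonResult",
    "ModelSpec",
    "c_index",
    "bootstrap_experiment",
    "compare_models",
    "subgroup_c_index",
    "finding_subgroups",
    "results_table",
    "comparison_matrix",
]


@dataclass(frozen=True)
class CIndexResult:
    """C-index with its pair bookkeeping (concordant includes 0.5 tie credit)."""

    value: float
    concordant_pairs: float
    comparable_pairs: int


def c_index(times, events, risks) -> CIndexResult:
    """Concordance of risk scores against right-censored outcomes.

    Orientation: higher risk must accompany shorter time.  Raises
    ``ValueError`` when no pair is comparable (e.g. everything censored).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    risks = np.asarray(risks, dtype=float)
    if not (times.shape == events.shape == risks.shape):
        raise ValueError("times, events and risks must have equal length")
    # comparable[j, i]: subject j died strictly earlier than i was observed
    shorter = times[:, None] < times[None, :]
    comparable = shorter & events[:, None]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pair (no event precedes another observation)")
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    concordant = float((comparable & higher).sum()) + 0.5 * float((comparable & tied).sum())
    return CIndexResult(
        value=concordant / n_comp, concordant_pairs=concordant, comparable_pairs=n_comp
    )


def finding_subgroups(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Masks for the standard breakdown: normal, abnormal, each finding."""
    labels = np.asarray(labels)
    groups = {
        "normal": labels[:, -1] == 1,
        "abnormal": labels[:, -1] == 0,
    }
    for j, name in enumerate(findings.DISEASES):
        groups[name] = labels[:, j] == 1
    return groups


def subgroup_c_index(
    times, events, risks, groups: Mapping[str, np.ndarray]
) -> dict[str, CIndexResult | None]:
    """C-index restricted to each subgroup mask.

    Degenerate subgroups (empty, or without a comparable pair) map to
    ``None`` rather than raising, so a batch of subgroups always completes.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    risks = np.asarray(risks, dtype=float)
    out: dict[str, CIndexResult | None] = {}
    for name, mask in groups.items():
        mask = np.asarray(mask, dtype=bool)
        try:
            out[name] = c_index(times[mask], events[mask], risks[mask])
        except ValueError:
            logger.warning("subgroup %r not evaluable (no comparable pair)", name)
            out[name] = None
    return out


# ---------------------------------------------------------------------------
# model specs


@dataclass(frozen=True)
class ModelSpec:
    """A named model entering the bootstrap grid.

    ``kind``:

    * ``"score"`` — no training; the risk score is the SAPS-II score itself
      (the traditional ICU scoring baseline);
    * ``"coxph"`` — linear Cox on the concatenation of the listed covariate
      blocks (``saps`` = 15 standardised factors, ``labels`` = the 13 disease
      indicators);
    * ``"deepsurv"`` — the fused neural risk model with ``fusion`` settings.
    """

    name: str
    kind: str
    covariates: tuple[str, ...] = ("saps",)
    fusion: FusionConfig | None = None

    def __post_init__(self):
        if self.kind not in ("score", "coxph", "deepsurv"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "deepsurv" and self.fusion is None:
            raise ValueError("deepsurv spec needs a FusionConfig")


@dataclass
class BootstrapResult:
    """Replicate-level test C-indexes plus summaries."""

    name: str
    replicate_values: np.ndarray
    mean: float
    ci95: tuple[float, float]
    n_replicates: int
    split_fractions: tuple[float, float, float]
    seeds: list[int] = field(default_factory=list)

    @staticmethod
    def from_values(
        name: str,
        values: np.ndarray,
        seeds: list[int],
        split_fractions=(0.70, 0.10, 0.20),
        ci_method: str = "percentile",
    ) -> "BootstrapResult":
        values = np.asarray(values, dtype=float)
        if ci_method == "percentile":
            ci = (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))
        elif ci_method == "normal":
            se = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else 0.0
            ci = (float(values.mean() - 1.96 * se), float(values.mean() + 1.96 * se))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        return BootstrapResult(
            name=name,
            replicate_values=values,
            mean=float(values.mean()),
            ci95=ci,
            n_replicates=len(values),
            split_fractions=tuple(split_fractions),
            seeds=list(seeds),
        )


def _split_indices(n, split_fractions, rng):
    order = rng.permutation(n)
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    return order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]


def _prepare_model_inputs(cohort: Cohort, spec: ModelSpec):
    """Encode the whole cohort once; replicates then index rows."""
    times, events = cohort.times, cohort.events
    if spec.kind == "score":
        return {"risks": cohort.saps_scores.astype(float), "times": times, "events": events}
    if spec.kind == "coxph":
        blocks = []
        names: list[str] = []
        for cov in spec.covariates:
            if cov == "saps":
                blocks.append(encode_modalities(cohort, ("saps",))["saps"])
                names += [f"saps_{i}" for i in range(15)]
            elif cov == "labels":
                blocks.append(cohort.labels[:, : findings.N_DISEASES].astype(float))
                names += list(findings.DISEASES)
            else:
                raise ValueError(f"unknown coxph covariate block {cov!r}")
        return {"X": np.column_stack(blocks), "names": names, "times": times, "events": events}
    # deepsurv
    gcn_params, a_hat = None, None
    if "gcn_text" in spec.fusion.enabled_modalities:
        graph = default_concept_graph()
        a_hat = normalize_adjacency(graph)
        gcn_params = GCNParams.initialize(
            n_nodes=graph.n_nodes, seed=spec.fusion.seed
        )
    feats = encode_modalities(
        cohort, spec.fusion.enabled_modalities, gcn_params=gcn_params, a_hat=a_hat
    )
    return {
        "features": feats,
        "times": times,
        "events": events,
        "gcn_params": gcn_params,
        "a_hat": a_hat,
    }


def _replicate_c_index(prep, spec: ModelSpec, idx, rng, rep_seed: int) -> float:
    times, events = prep["times"][idx], prep["events"][idx]
    n = len(idx)
    tr, va, te = _split_indices(n, (0.70, 0.10, 0.20), rng)
    if spec.kind == "score":
        risks = prep["risks"][idx]
        return c_index(times[te], events[te], risks[te]).value
    if spec.kind == "coxph":
        X = prep["X"][idx]
        model = fit_linear_cox(X[tr], times[tr], events[tr], names=prep["names"])
        risks = model.predict_risk(X[te])
        return c_index(times[te], events[te], risks).value
    feats = {m: F[idx] for m, F in prep["features"].items()}
    cfg = dataclasses.replace(spec.fusion, seed=rep_seed)
    model = train_on_arrays(
        {m: F[tr] for m, F in feats.items()},
        times[tr],
        events[tr],
        {m: F[va] for m, F in feats.items()},
        times[va],
        events[va],
        cfg,
        gcn_params=prep["gcn_params"],
        a_hat=prep["a_hat"],
    )
    risks = risk_forward_batch(model, {m: F[te] for m, F in feats.items()})
    return c_index(times[te], events[te], risks).value


def bootstrap_experiment(
    cohort: Cohort,
    model_spec: ModelSpec,
    n_replicates: int = 200,
    seed: int = 0,
    *,
    split_fractions=(0.70, 0.10, 0.20),
    ci_method: str = "percentile",
    max_redraws: int = 10,
) -> BootstrapResult:
    """Bootstrap distribution of the test C-index for one model.

    Each replicate resamples ``n`` subjects with replacement, splits
    train/validation/test per ``split_fractions``, trains and scores.  A
    replicate with a degenerate test split (no comparable pair) or a
    degenerate training fit is redrawn with a perturbed seed (logged); more
    than ``max_redraws`` consecutive failures raises.
    """
    n = len(cohort)
    prep = _prepare_model_inputs(cohort, model_spec)
    values, seeds = [], []
    for r in range(n_replicates):
        for attempt in range(max_redraws + 1):
            rep_seed = r if attempt == 0 else r + 100_000 * attempt
            rng = np.random.default_rng([seed, 21, rep_seed])
            idx = rng.integers(0, n, size=n)
            try:
                value = _replicate_c_index(prep, model_spec, idx, rng, rep_seed)
            except (ValueError, ConvergenceError) as exc:
                logger.warning(
                    "replicate %d attempt %d failed (%s); redrawing", r, attempt, exc
                )
                continue
            values.append(value)
            seeds.append(rep_seed)
            break
        else:
            raise RuntimeError(
                f"replicate {r} failed {max_redraws + 1} times; cohort too degenerate"
            )
    return BootstrapResult.from_values(
        model_spec.name, np.array(values), seeds, split_fractions, ci_method
    )


# ---------------------------------------------------------------------------
# paired comparison


@dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of two bootstrap distributions (b minus a)."""

    p_value: float
    mean_difference: float
    direction: str  # "b>a", "a>b" or "tie"
    method: str


def compare_models(
    a: BootstrapResult, b: BootstrapResult, method: str = "wilcoxon"
) -> ComparisonResult:
    """Two-sided paired test on per-replicate C-index differences.

    Requires both results to come from the same replicate seeds (a paired
    design); ``method`` is ``"wilcoxon"`` (signed-rank, default) or
    ``"ttest"``.
    """
    if a.seeds != b.seeds:
        raise ValueError("bootstrap results are not paired (replicate seeds differ)")
    diffs = b.replicate_values - a.replicate_values
    mean_diff = float(diffs.mean())
    if np.allclose(diffs, 0):
        return ComparisonResult(1.0, 0.0, "tie", method)
    if method == "wilcoxon":
        stat = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
        p = float(stat.pvalue)
    elif method == "ttest":
        p = float(stats.ttest_rel(b.replicate_values, a.replicate_values).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = "b>a" if mean_diff > 0 else ("a>b" if mean_diff < 0 else "tie")
    return ComparisonResult(p, mean_diff, direction, method)


# ---------------------------------------------------------------------------
# result tables


def results_table(results: list[BootstrapResult]) -> pd.DataFrame:
    """Model-by-row summary: mean C-index and 95% CI bounds."""
    return pd.DataFrame(
        {
            "model": [r.name for r in results],
            "mean_c_index": [r.mean for r in results],
            "ci_lower": [r.ci95[0] for r in results],
            "ci_upper": [r.ci95[1] for r in results],
            "n_replicates": [r.n_replicates for r in results],
        }
    )


def comparison_matrix(results: list[BootstrapResult], method: str = "wilcoxon") -> pd.DataFrame:
    """Symmetric matrix of pairwise paired p-values."""
    names = [r.name for r in results]
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, ra in enumerate(results):
        for j, rb in enumerate(results):
            if i < j:
                p = compare_models(ra, rb, method=method).p_value
                mat.iloc[i, j] = mat.iloc[j, i] = p
    return mat
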