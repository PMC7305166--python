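"""End-to-end orchestration of the IPFP-volume modelling study.

Stages: BMI/gender stratification → PSOBVS variable selection with AIC size
choice → neuro-fuzzy model fits of the selected 5-variable model ("model
#5") per group → feature-ablation grid → gender-separation comparison →
inverse-ratio study → external-cohort validation → rule-base ("pseudocode")
export.  Every stage flows from one master seed; train/test provenance is
carried on the fitted models so that validation data can be asserted
disjoint from training data at run time.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as mx
from .anfis import FISModel, TrainConfig, evaluate_fis, fit_anfis
from .features import (
    FEATURE_NAMES,
    FeatureMatrix,
    build_features,
    invert_ratios,
)
from .selection import (
    SizeSelection,
    SwarmConfig,
    aic_score,
    holdout_sse,
    monte_carlo_select,
)

#: Published composition of the best 5-variable model per stratum.  The
#: shared core is age, gender, BMI and adipsin/CRP; the fifth member is
#: stratum-specific.  Names resolve through FeatureMatrix (orientation-
#: insensitive for ratios).
MODEL5: dict[str, tuple[str, ...]] = {
    "Total": ("age", "gender", "bmi", "adipsin/CRP", "adipsin/chemerin"),
    "HighBMI": ("age", "gender", "bmi", "adipsin/CRP", "chemerin/adiponectin_HMW"),
    "LowBMI": ("age", "gender", "bmi", "adipsin/CRP", "IL8"),
}

DEFAULT_BMI_CUT = 30.0


@dataclass(frozen=True)
class StudyConfig:
    bmi_cut: float = DEFAULT_BMI_CUT
    groups: tuple[str, ...] = ("Total", "HighBMI", "LowBMI")
    subset_sizes: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    seed: int = 0
    swarm: SwarmConfig = SwarmConfig()
    train: TrainConfig = TrainConfig(n_rules=3)
    train_fraction: float = 0.7

    def __post_init__(self):
        if self.bmi_cut <= 0:
            raise ValueError("bmi_cut must be positive")
        if not self.groups:
            raise ValueError("at least one group required")


# ---------------------------------------------------------------------------
# stratification and splits
# ---------------------------------------------------------------------------


def stratify(cohort: pd.DataFrame, bmi_cut: float = DEFAULT_BMI_CUT) -> dict[str, pd.DataFrame]:
    """Total / High-BMI (BMI ≥ cut, inclusive) / Low-BMI subcohorts."""
    high = cohort[cohort["bmi"] >= bmi_cut]
    low = cohort[cohort["bmi"] < bmi_cut]
    out = {"Total": cohort, "HighBMI": high, "LowBMI": low}
    return {k: v for k, v in out.items() if len(v) > 0}


def split_gender(subcohort: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """{0: female rows, 1: male rows}."""
    return {g: subcohort[subcohort["gender"] == g] for g in (0, 1)}


def train_test_split_idx(
    n: int, seed: int, train_fraction: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """One shuffled 70/30 split as positional indices."""
    perm = np.random.default_rng(seed).permutation(n)
    n_tr = int(round(train_fraction * n))
    return np.sort(perm[:n_tr]), np.sort(perm[n_tr:])


def _ids_digest(ids) -> str:
    h = hashlib.sha256()
    for s in sorted(map(str, ids)):
        h.update(s.encode())
        h.update(b"\0")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# model fitting with provenance
# ---------------------------------------------------------------------------


def fit_group_model(
    fm: FeatureMatrix,
    y: np.ndarray,
    subset: tuple[str, ...],
    cfg: StudyConfig,
    train_idx: np.ndarray,
) -> FISModel:
    """Fit the neuro-fuzzy predictor on the training rows of a subset."""
    X = fm.matrix(subset)
    model = fit_anfis(
        X[train_idx], y[train_idx], cfg=replace(cfg.train, seed=cfg.seed),
        input_names=list(subset),
    )
    train_ids = [str(s) for s in fm.subject_ids.iloc[train_idx]]
    model.provenance = {
        "train_subject_ids": sorted(train_ids),
        "train_ids_sha256": _ids_digest(train_ids),
        "seed": cfg.seed,
    }
    return model


def _eval_split(
    model: FISModel, fm: FeatureMatrix, y: np.ndarray, idx: np.ndarray
) -> mx.MetricSet:
    pred = model.predict(fm.matrix(model.input_names)[idx])
    return mx.compute_metrics(y[idx], pred)


# ---------------------------------------------------------------------------
# variable selection per group
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Per-size winners, AIC values, Monte-Carlo frequencies, overall winner."""

    group: str
    feature_names: tuple[str, ...]
    by_size: dict[int, SizeSelection]
    winner_size: int
    winner_subset: tuple[str, ...]
    seed: int

    def subset_names(self, m: int) -> tuple[str, ...]:
        return tuple(self.feature_names[i] for i in self.by_size[m].subset)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "seed": self.seed,
            "winner_size": self.winner_size,
            "winner_subset": list(self.winner_subset),
            "by_size": {
                str(m): {
                    "subset": list(self.subset_names(m)),
                    "fitness": sel.fitness,
                    "aic": sel.aic,
                    "selection_frequency": {
                        self.feature_names[i]: float(f)
                        for i, f in enumerate(sel.frequencies)
                        if f > 0
                    },
                }
                for m, sel in sorted(self.by_size.items())
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def run_selection(
    subcohort: pd.DataFrame,
    cfg: StudyConfig,
    group: str = "Total",
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> SelectionResult:
    """Monte-Carlo PSOBVS at each subset size, then AIC picks the winner.

    The search only ever sees the 70% training split; the AIC comparison
    across sizes uses each winner's OLS error on the untouched 30% holdout
    (see :func:`ipfpvol.selection.holdout_sse` for why in-sample SSE would
    bias the size choice upward).
    """
    fm = build_features(subcohort)
    X = fm.matrix(feature_names)
    y = subcohort["ipfp_volume"].to_numpy(dtype=float)
    tr, te = train_test_split_idx(len(y), cfg.seed, cfg.train_fraction)

    by_size: dict[int, SizeSelection] = {}
    for m in cfg.subset_sizes:
        sel = monte_carlo_select(
            X[tr], y[tr], m, replace(cfg.swarm, subset_size=m, seed=cfg.seed + m)
        )
        sse = holdout_sse(X[tr], y[tr], X[te], y[te], sel.subset)
        sel.aic = aic_score(len(te), sse, p=m + 1)
        by_size[m] = sel

    winner_size = min(by_size, key=lambda m: by_size[m].aic)
    result = SelectionResult(
        group=group,
        feature_names=tuple(feature_names),
        by_size=by_size,
        winner_size=winner_size,
        winner_subset=tuple(feature_names[i] for i in by_size[winner_size].subset),
        seed=cfg.seed,
    )
    return result


# ---------------------------------------------------------------------------
# ablation grid (Table-1-style M1..M25 view over 26 enumerated models)
# ---------------------------------------------------------------------------


@dataclass
class AblationEntry:
    label: str  # M1..M26 (M26 is absent from the published 25-model table)
    features: tuple[str, ...]
    metrics: mx.MetricSet
    taylor: mx.TaylorStats
    in_published_view: bool


@dataclass
class AblationGrid:
    group: str
    base_subset: tuple[str, ...]
    entries: list[AblationEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": e.label,
                    "n_features": len(e.features),
                    "features": "+".join(e.features),
                    "R": e.metrics.R,
                    "SI": e.metrics.SI,
                    "MAPE": e.metrics.MAPE,
                    "RMSRE": e.metrics.RMSRE,
                    "taylor_std_ratio": e.taylor.std_ratio,
                    "taylor_crms": e.taylor.crms,
                    "in_published_view": e.in_published_view,
                }
                for e in self.entries
            ]
        )


def run_ablation(
    subcohort: pd.DataFrame,
    base_subset: tuple[str, ...],
    cfg: StudyConfig,
    group: str = "Total",
) -> AblationGrid:
    """Fit a model per sub-subset (sizes 5 down to 2) of the 5-variable base.

    Full enumeration yields 1 + 5 + 10 + 10 = 26 models.  The published
    25-model grid lists only 9 of the C(5,3) = 10 three-variable models;
    the last enumerated three-variable model is therefore flagged as
    outside that view (which one was omitted is not recoverable).
    All models share the same train/test split.
    """
    if len(base_subset) != 5:
        raise ValueError("base subset must have exactly 5 features")
    fm = build_features(subcohort)
    y = subcohort["ipfp_volume"].to_numpy(dtype=float)
    tr, te = train_test_split_idx(len(y), cfg.seed, cfg.train_fraction)

    subsets: list[tuple[str, ...]] = [tuple(base_subset)]
    for size in (4, 3, 2):
        subsets.extend(itertools.combinations(base_subset, size))

    entries: list[AblationEntry] = []
    n_three_seen = 0
    for i, subset in enumerate(subsets, start=1):
        model = fit_group_model(fm, y, subset, cfg, tr)
        pred = model.predict(fm.matrix(subset)[te])
        published = True
        if len(subset) == 3:
            n_three_seen += 1
            published = n_three_seen <= 9  # published table stops at M15
        entries.append(
            AblationEntry(
                label=f"M{i}",
                features=subset,
                metrics=mx.compute_metrics(y[te], pred),
                taylor=mx.taylor_stats(y[te], pred),
                in_published_view=published,
            )
        )
    return AblationGrid(group=group, base_subset=tuple(base_subset), entries=entries)


# ---------------------------------------------------------------------------
# gender separation
# ---------------------------------------------------------------------------


@dataclass
class GenderComparison:
    group: str
    pooled: dict[int, mx.MetricSet]  # per-gender test metrics of the pooled model
    separate: dict[int, mx.MetricSet]
    mape_improvement_pct: dict[int, float]  # 100·(pooled − separate)/pooled
    split_digest: str

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "split_digest": self.split_digest,
            "pooled": {str(g): m.to_dict() for g, m in self.pooled.items()},
            "separate": {str(g): m.to_dict() for g, m in self.separate.items()},
            "mape_improvement_pct": {
                str(g): v for g, v in self.mape_improvement_pct.items()
            },
        }


def run_gender_comparison(
    subcohort: pd.DataFrame,
    subset: tuple[str, ...],
    cfg: StudyConfig,
    group: str = "Total",
    min_stratum: int = 20,
) -> GenderComparison:
    """Pooled vs gender-specific models on identical row-level splits.

    One 70/30 split is drawn on the full stratum; the gender-specific models
    train and test on the gender-restricted rows of that same split, so the
    comparison differs only in model separation, never in data routing.
    """
    fm = build_features(subcohort)
    y = subcohort["ipfp_volume"].to_numpy(dtype=float)
    gender = subcohort["gender"].to_numpy()
    tr, te = train_test_split_idx(len(y), cfg.seed, cfg.train_fraction)
    for g in (0, 1):
        if (gender == g).sum() < min_stratum:
            raise ValueError(f"gender stratum {g} below minimum size {min_stratum}")

    pooled_model = fit_group_model(fm, y, subset, cfg, tr)
    X = fm.matrix(subset)
    pooled, separate, improvement = {}, {}, {}
    for g in (0, 1):
        te_g = te[gender[te] == g]
        tr_g = tr[gender[tr] == g]
        pooled[g] = mx.compute_metrics(y[te_g], pooled_model.predict(X[te_g]))
        sep_model = fit_group_model(fm, y, subset, cfg, tr_g)
        separate[g] = mx.compute_metrics(y[te_g], sep_model.predict(X[te_g]))
        improvement[g] = 100.0 * (pooled[g].MAPE - separate[g].MAPE) / pooled[g].MAPE
    return GenderComparison(
        group=group,
        pooled=pooled,
        separate=separate,
        mape_improvement_pct=improvement,
        split_digest=_ids_digest(fm.subject_ids.iloc[tr]),
    )


# ---------------------------------------------------------------------------
# inverse-ratio study
# ---------------------------------------------------------------------------


@dataclass
class InverseRatioStudy:
    group: str
    subset: tuple[str, ...]
    main: mx.MetricSet
    inverse: mx.MetricSet
    test_ids_digest: str


def _flip_name(name: str) -> str:
    if "/" in name:
        num, den = name.split("/", 1)
        return f"{den}/{num}"
    return name


def run_inverse_ratio_study(
    subcohort: pd.DataFrame,
    subset: tuple[str, ...],
    cfg: StudyConfig,
    group: str = "Total",
) -> InverseRatioStudy:
    """Twin fits on main-form vs reciprocal-form ratios, identical splits."""
    fm_main = build_features(subcohort)
    fm_inv = invert_ratios(fm_main)
    subset_inv = tuple(_flip_name(s) for s in subset)
    y = subcohort["ipfp_volume"].to_numpy(dtype=float)
    tr, te = train_test_split_idx(len(y), cfg.seed, cfg.train_fraction)

    out = {}
    for tag, fm, sub in (("main", fm_main, subset), ("inverse", fm_inv, subset_inv)):
        model = fit_group_model(fm, y, sub, cfg, tr)
        pred = model.predict(fm.matrix(sub)[te])
        out[tag] = mx.compute_metrics(y[te], pred)
    return InverseRatioStudy(
        group=group,
        subset=tuple(subset),
        main=out["main"],
        inverse=out["inverse"],
        test_ids_digest=_ids_digest(fm_main.subject_ids.iloc[te]),
    )


# ---------------------------------------------------------------------------
# external validation and pseudocode export
# ---------------------------------------------------------------------------


def validate_external(
    model: FISModel, cohort: pd.DataFrame
) -> tuple[mx.MetricSet, mx.UncertaintyReport, pd.DataFrame]:
    """Pure held-out evaluation; refuses any overlap with training subjects."""
    train_ids = set(model.provenance.get("train_subject_ids", []))
    cohort_ids = set(map(str, cohort["subject_id"]))
    overlap = train_ids & cohort_ids
    if overlap:
        raise ValueError(
            f"validation cohort shares {len(overlap)} subject(s) with training data"
        )
    fm = build_features(cohort)
    for name in model.input_names:
        if not fm.has(name):
            raise KeyError(f"feature {name!r} missing from validation cohort")
    X = fm.matrix(model.input_names)
    y = cohort["ipfp_volume"].to_numpy(dtype=float)
    pred = model.predict(X)
    scatter = pd.DataFrame(
        {"subject_id": cohort["subject_id"].to_numpy(), "observed": y, "predicted": pred}
    )
    return mx.compute_metrics(y, pred), mx.uncertainty_band(y, pred), scatter


def export_pseudocode(model: FISModel, path) -> None:
    """Write the rule base as JSON plus a human-readable algorithm listing.

    ``path`` is the stem: ``<path>.json`` holds the machine-readable model
    (round-trips predictions bit-for-bit), ``<path>.txt`` the rule-by-rule
    IF/THEN listing in scaled-input coordinates with the scaler stated.
    """
    path = str(path)
    model.to_json(path + ".json")
    lines = [
        "IPFP volume prediction — first-order Takagi–Sugeno rule base",
        f"inputs: {', '.join(model.input_names)}",
        "scale each input: z_i = (x_i - mean_i) / sd_i with",
    ]
    for name, mu, sd in zip(model.input_names, model.scaler_mean, model.scaler_scale):
        lines.append(f"    {name}: mean = {mu!r}, sd = {sd!r}")
    lines.append("")
    for r in range(model.n_rules):
        conds = " AND ".join(
            f"z_{name} is Gaussian(center={model.centers[r, j]!r}, width={model.widths[r, j]!r})"
            for j, name in enumerate(model.input_names)
        )
        terms = " + ".join(
            f"({model.coefs[r, j]!r})*z_{name}"
            for j, name in enumerate(model.input_names)
        )
        lines.append(f"RULE {r + 1}:")
        lines.append(f"  IF {conds}")
        lines.append(f"  THEN volume_{r + 1} = {terms} + ({model.intercepts[r]!r})")
        lines.append("")
    lines.append(
        "prediction = sum_r w_r * volume_r, w_r = exp(-0.5*sum_j((z_j-center_rj)/width_rj)^2),"
    )
    lines.append("normalized so that sum_r w_r = 1.")
    with open(path + ".txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_pseudocode(path) -> FISModel:
    return FISModel.from_json(str(path) + ".json")
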