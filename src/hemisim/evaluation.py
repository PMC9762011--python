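"""Performance metrics, the gated comparison pipeline, sweeps, recommendations.

Performance is the Reaching Error (RE): the Euclidean distance between the
target and the achieved hand endpoint, averaged over the test grid.  Targets
with RE above a threshold of 0.06 (one tenth of the arm length) count as
inaccessible.  Group comparisons follow the two-branch procedure: a Levene
test gates between one-way ANOVA + Tukey HSD (homogeneous variances) and
Welch ANOVA + Dunn-Bonferroni post-hoc tests (heterogeneous variances), with
significance at p = 0.05.  The statistical unit is the per-seed mean RE of
the paretic arm across independently initialised models.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .kinematics import reaching_error

ACCESSIBILITY_THRESHOLD = 0.06  # one tenth of the 0.6 arm length
P_SIG = 0.05


@dataclass
class EvaluationResult:
    """Per-target reaching errors and accessibility counts for one model."""

    re_left: np.ndarray            # RE of the left arm per evaluated sample
    re_right: np.ndarray
    active_left: np.ndarray        # bool: left arm required to reach the target
    active_right: np.ndarray
    threshold: float
    labels: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def mean_re_left(self) -> float:
        return float(np.mean(self.re_left[self.active_left]))

    @property
    def mean_re_right(self) -> float:
        return float(np.mean(self.re_right[self.active_right]))

    def accessibility(self, arm: str = "left") -> tuple[int, int]:
        """(accessible, inaccessible) target counts for one arm's active samples."""
        re = self.re_left[self.active_left] if arm == "left" else self.re_right[self.active_right]
        inaccessible = int(np.sum(re > self.threshold))
        return len(re) - inaccessible, inaccessible


def evaluate(
    model,
    dataset,
    threshold: float = ACCESSIBILITY_THRESHOLD,
    exclude_rest: bool = True,
    labels: dict | None = None,
    chunk_size: int = 512,
) -> EvaluationResult:
    """Forward the test set and score per-target reaching errors.

    ``exclude_rest`` drops HSP [0 0] samples (the convention for all stroke
    analyses; rest performance is unaffected by the lesion).  Mean RE per arm
    is taken over the samples in which that arm is active.
    """
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if exclude_rest:
        dataset = dataset.without_rest_mode()
        if len(dataset) == 0:
            raise ValueError("dataset contains only HSP [0 0] samples")
    n = len(dataset)
    re = {"left": np.empty(n), "right": np.empty(n)}
    req = {"left": dataset.required_left, "right": dataset.required_right}
    for start in range(0, n, chunk_size):
        sl = np.arange(start, min(start + chunk_size, n))
        hands = model.predict_hands(dataset.batch_images(sl), dataset.hsp[sl])
        for arm in ("left", "right"):
            re[arm][sl] = reaching_error(req[arm][sl], hands[arm])
    return EvaluationResult(
        re_left=re["left"],
        re_right=re["right"],
        active_left=dataset.hsp[:, 0] == 1,
        active_right=dataset.hsp[:, 1] == 1,
        threshold=threshold,
        labels=labels or {},
    )


# --------------------------------------------------------------------- stats
@dataclass
class ComparisonReport:
    """Levene-gated omnibus + post-hoc comparison of labelled groups."""

    group_labels: list
    levene_p: float
    anova_p: float
    method: str                   # 'anova+tukey' or 'welch+dunn-bonferroni'
    posthoc: pd.DataFrame         # columns: group1, group2, p_value, significant
    p_sig: float = P_SIG

    @property
    def significant(self) -> bool:
        return self.anova_p < self.p_sig

    def posthoc_p(self, a: str, b: str) -> float:
        for _, row in self.posthoc.iterrows():
            if {row["group1"], row["group2"]} == {a, b}:
                return float(row["p_value"])
        raise KeyError(f"no post-hoc comparison between {a!r} and {b!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "group_labels": list(self.group_labels),
                "levene_p": self.levene_p,
                "anova_p": self.anova_p,
                "method": self.method,
                "posthoc": self.posthoc.to_dict(orient="records"),
                "p_sig": self.p_sig,
            },
            indent=2,
        )


def _dunn_bonferroni(groups: dict) -> pd.DataFrame:
    """Dunn's rank-based pairwise tests with Bonferroni correction."""
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(values)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for label, v in zip(labels, values):
        mean_ranks[label] = float(np.mean(ranks[start : start + len(v)]))
        sizes[label] = len(v)
        start += len(v)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rows = []
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * len(pairs))
        rows.append({"group1": a, "group2": b, "p_value": p, "significant": p < P_SIG})
    return pd.DataFrame(rows)


def compare_groups(groups: dict, p_sig: float = P_SIG) -> ComparisonReport:
    """Compare labelled collections of per-seed mean REs.

    Levene's test (centred on the mean) gates the branch: homogeneous
    variances -> one-way ANOVA with Tukey HSD post-hoc; heterogeneous ->
    Welch ANOVA with Dunn-Bonferroni post-hoc.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    labels = list(arrays)
    _, levene_p = stats.levene(*arrays.values(), center="mean")
    long = pd.DataFrame(
        {
            "value": np.concatenate(list(arrays.values())),
            "group": np.repeat(labels, [len(arrays[k]) for k in labels]),
        }
    )
    if levene_p > p_sig:
        _, anova_p = stats.f_oneway(*arrays.values())
        tukey = pg.pairwise_tukey(data=long, dv="value", between="group")
        posthoc = pd.DataFrame(
            {
                "group1": tukey["A"],
                "group2": tukey["B"],
                "p_value": tukey["p_tukey"].astype(float),
            }
        )
        posthoc["significant"] = posthoc["p_value"] < p_sig
        method = "anova+tukey"
    else:
        welch = pg.welch_anova(data=long, dv="value", between="group")
        anova_p = float(welch["p_unc"].iloc[0])
        posthoc = _dunn_bonferroni(arrays)
        method = "welch+dunn-bonferroni"
    return ComparisonReport(
        group_labels=labels,
        levene_p=float(levene_p),
        anova_p=float(anova_p),
        method=method,
        posthoc=posthoc,
        p_sig=p_sig,
    )


# --------------------------------------------------------------------- sweep
def _cell_key(**kwargs) -> str:
    return hashlib.sha1(json.dumps(kwargs, sort_keys=True).encode()).hexdigest()[:16]


def run_sweep(
    base_seeds,
    lesion_sizes=(5, 10, 15, 20),
    stages=("acute",),
    cc_integrities=(1.0,),
    therapies=None,
    profile=None,
    cache_dir=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Full experiment grid: conditions x therapies x seeds -> tidy table.

    One row per (seed, stage, lesion size, integrity, therapy); results are
    cached by configuration hash when ``cache_dir`` is given, so an
    interrupted sweep resumes.  Columns: seed, stage, lesion_size,
    cc_integrity, complexity, hand_mode, plasticity, mean_re_left,
    mean_re_right, n_inaccessible.
    """
    from . import pipeline
    from .therapy import TherapyConfig

    if profile is None:
        profile = pipeline.desk_profile()
    if therapies is None:
        therapies = [
            TherapyConfig(complexity=c, hand_mode=m, plasticity=p)
            for c in ("stereotypic", "exploratory")
            for m in ("cimt", "bmt")
            for p in ("local", "global")
        ]
    cache = pathlib.Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for seed in base_seeds:
        ctx = None  # lazily trained healthy model + test set for this seed
        for stage in stages:
            for n_lesion in lesion_sizes:
                for integrity in cc_integrities:
                    for therapy in therapies:
                        key = _cell_key(
                            seed=int(seed),
                            stage=stage,
                            lesion=int(n_lesion),
                            integrity=float(integrity),
                            therapy=[therapy.complexity, therapy.hand_mode, therapy.plasticity],
                            profile=profile.hash(),
                        )
                        cached_file = cache / f"{key}.json" if cache else None
                        if cached_file is not None and cached_file.exists():
                            rows.append(json.loads(cached_file.read_text()))
                            continue
                        if ctx is None:
                            ctx = pipeline.SeedContext.create(profile, int(seed))
                        row = pipeline.run_cell(ctx, stage, int(n_lesion), float(integrity), therapy)
                        if progress:
                            print(
                                f"seed={seed} {stage} n={n_lesion} p={integrity} "
                                f"{therapy.complexity}/{therapy.hand_mode}/{therapy.plasticity}: "
                                f"RE_left={row['mean_re_left']:.4f}"
                            )
                        if cached_file is not None:
                            cached_file.write_text(json.dumps(row))
                        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------- recommendations
def recommend_protocol(results: pd.DataFrame) -> pd.DataFrame:
    """Optimal plasticity extent per (stage, lesion size, CC integrity).

    Global plasticity is recommended only where it is significantly better
    (post-hoc p < 0.05 and lower mean paretic-arm RE) than local under at
    least one hand-selection mode; otherwise local — ties go to the cheaper
    protocol.  Only exploratory-therapy rows enter the comparison.
    """
    df = results[results["complexity"] == "exploratory"]
    required = {"local", "global"}
    rows = []
    for (stage, n_lesion, integrity), cond in df.groupby(["stage", "lesion_size", "cc_integrity"]):
        if set(cond["plasticity"].unique()) != required:
            raise ValueError(
                f"condition ({stage}, {n_lesion}, {integrity}) is missing a plasticity arm"
            )
        prefer_global = False
        for mode, sub in cond.groupby("hand_mode"):
            groups = {
                p: sub.loc[sub["plasticity"] == p, "mean_re_left"].to_numpy()
                for p in ("local", "global")
            }
            if min(len(v) for v in groups.values()) < 2:
                raise ValueError("need >= 2 seeds per plasticity arm")
            report = compare_groups(groups)
            better = groups["global"].mean() < groups["local"].mean()
            if better and report.posthoc_p("local", "global") < P_SIG:
                prefer_global = True
        rows.append(
            {
                "stage": stage,
                "lesion_size": n_lesion,
                "cc_integrity": integrity,
                "recommended_plasticity": "global" if prefer_global else "local",
            }
        )
    return pd.DataFrame(rows)
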