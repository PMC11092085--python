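"""Statistical layer: correlation, group tests, ROC/Youden, BSS summaries.

Also ships the packaged cohort fixtures (genotype table, methylation table,
and the printed allele-specific upstream values) and
:func:`replicate_table2`, which recomputes the headline diagnostic
statistics from them:

* case/control mean methylation of the *DUX4* upstream and gene-body regions,
* Pearson correlations between the long-read region means and the clone
  bisulfite (BSS) means,
* a per-allele ROC over the 16 pathogenetic and 15 non-pathogenetic
  upstream values (sample-level values for single-4qA samples, printed
  read-level values for dual-4qA samples), with the Youden-optimal cut-off,
* a per-sample ROC over the 24 available BSS means.

The ROC orientation treats *lower* methylation as the positive
(pathogenetic) signal.  AUC is computed by pair ordering (Mann-Whitney, ties
0.5) and equals the trapezoidal area under the constructed curve.  The
Youden cut-off maximises sensitivity + specificity - 1 and is reported as
the midpoint of the two adjacent observed values bracketing the optimal
interval; ties prefer the more sensitive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

FIXTURES = resources.files("nanofshd") / "fixtures"


@dataclass(frozen=True)
class LabeledValue:
    unit_id: str
    value: float  # percent
    label: str  # "pathogenetic" | "non_pathogenetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError(f"value must be a percentage in [0, 100]: {self.value}")


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: list[tuple[float, float]]  # (fpr, tpr), from (0,0) to (1,1)

    @property
    def trapezoid_auc(self) -> float:
        fpr = np.array([p[0] for p in self.curve])
        tpr = np.array([p[1] for p in self.curve])
        return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# Basic statistics
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p-value; pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def _check_roc_input(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(v) != len(y):
        raise ValueError("values and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    return v, y


def roc(values, labels, lower_is_positive: bool = True) -> RocResult:
    """ROC over scalar values; ``labels`` True for the positive class.

    AUC by pair counting with ties worth 0.5.  The curve sweeps thresholds
    over the observed values (positives predicted where value < threshold
    when ``lower_is_positive``).
    """
    v, y = _check_roc_input(values, labels)
    score = -v if lower_is_positive else v
    pos, neg = score[y], score[~y]
    # Mann-Whitney pair counting
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    auc = (gt + 0.5 * eq) / (len(pos) * len(neg))

    # stepwise curve over descending score thresholds (predict positive if
    # score >= threshold), ties handled by grouping equal scores
    order = np.argsort(-score, kind="stable")
    ys = y[order]
    ss = score[order]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    n = len(ss)
    while i < n:
        j = i
        while j < n and ss[j] == ss[i]:
            j += 1
        tp += int(ys[i:j].sum())
        fp += (j - i) - int(ys[i:j].sum())
        tpr.append(tp / len(pos))
        fpr.append(fp / len(neg))
        i = j
    curve = list(zip(fpr, tpr))
    cutoff, sens, spec = youden_cutoff(values, labels, lower_is_positive)
    return RocResult(float(auc), cutoff, sens, spec, curve)


def youden_cutoff(
    values, labels, lower_is_positive: bool = True
) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximising Youden's J.

    Candidate thresholds are midpoints between adjacent distinct observed
    values (plus open ends); with ``lower_is_positive`` a unit is predicted
    positive when its value is below the cut-off.  J ties prefer the
    threshold with the higher sensitivity.
    """
    v, y = _check_roc_input(values, labels)
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    best = None
    for c in candidates:
        pred = v < c if lower_is_positive else v > c
        sens = float((pred & y).sum() / y.sum())
        spec = float((~pred & ~y).sum() / (~y).sum())
        j = sens + spec - 1.0
        key = (j, sens)
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    _, cutoff, sens, spec = best
    return cutoff, sens, spec


# ---------------------------------------------------------------------------
# Clone bisulfite (BSS) summaries
# ---------------------------------------------------------------------------

def bss_summarize(clone_table) -> tuple[np.ndarray, float]:
    """(per-site percent methylation, unweighted mean over sites).

    ``clone_table`` is clones x sites with binary entries; the per-site level
    is the ratio of methylated clones, and the summary value is the plain
    average of the per-site levels.
    """
    t = np.asarray(clone_table)
    if t.ndim != 2 or t.shape[0] < 1:
        raise ValueError("clone table must be 2-D with at least one clone")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("clone table entries must be 0/1")
    site_percent = 100.0 * t.mean(axis=0)
    return site_percent, float(site_percent.mean())


# ---------------------------------------------------------------------------
# Fixtures and the cohort replication driver
# ---------------------------------------------------------------------------

def load_table2(path: str | Path | None = None) -> pd.DataFrame:
    src = Path(path) if path else FIXTURES / "table2.tsv"
    with resources.as_file(src) if not isinstance(src, Path) else _nullctx(src) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    required = {"sample", "group", "upstream", "gene_body", "bss"}
    if not required.issubset(df.columns):
        raise ValueError(f"methylation fixture must have columns {sorted(required)}")
    return df


def load_allele_specific(path: str | Path | None = None) -> pd.DataFrame:
    src = Path(path) if path else FIXTURES / "allele_specific.tsv"
    with resources.as_file(src) if not isinstance(src, Path) else _nullctx(src) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    src = Path(path) if path else FIXTURES / "table1.tsv"
    with resources.as_file(src) if not isinstance(src, Path) else _nullctx(src) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)


class _nullctx:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def per_allele_upstream_values(
    table2: pd.DataFrame, allele_specific: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(values, labels) for the per-allele upstream ROC.

    Dual-4qA samples contribute their two printed read-level values (one
    pathogenetic, one not); every other case sample contributes its
    sample-level upstream value as a pathogenetic-allele value, and every
    control with a 4qA allele contributes its sample-level value as
    non-pathogenetic.
    """
    dual = set(allele_specific["sample"])
    values, labels = [], []
    for _, r in table2.iterrows():
        if pd.isna(r["upstream"]) or r["sample"] in dual:
            continue
        values.append(float(r["upstream"]))
        labels.append(r["group"] == "case")
    for _, r in allele_specific.iterrows():
        values.append(float(r["upstream_percent"]))
        labels.append(bool(int(r["pathogenetic"])))
    return np.asarray(values), np.asarray(labels)


def replicate_table2(
    table2_path: str | Path | None = None,
    allele_specific_path: str | Path | None = None,
) -> dict:
    """Recompute the cohort's diagnostic statistics from the packaged fixtures.

    Fully deterministic; returns a nested dict (percent scales throughout).
    """
    t2 = load_table2(table2_path)
    aspec = load_allele_specific(allele_specific_path)

    cases = t2[t2["group"] == "case"]
    controls = t2[(t2["group"] == "control") & t2["upstream"].notna()]

    means = dict(
        case_upstream=round(float(cases["upstream"].mean()), 2),
        control_upstream=round(float(controls["upstream"].mean()), 2),
        case_gene_body=round(float(cases["gene_body"].mean()), 2),
        control_gene_body=round(float(controls["gene_body"].mean()), 2),
    )

    both = t2[t2["upstream"].notna()]
    r_up_gb, p_up_gb = pearson(both["upstream"], both["gene_body"])
    r_up_bss, p_up_bss = pearson(both["upstream"], both["bss"])

    values, labels = per_allele_upstream_values(t2, aspec)
    allele_roc = roc(values, labels, lower_is_positive=True)

    bss = t2[t2["bss"].notna()]
    bss_roc = roc(
        bss["bss"].to_numpy(), (bss["group"] == "case").to_numpy(),
        lower_is_positive=True,
    )

    return dict(
        group_means=means,
        pearson=dict(
            upstream_gene_body=dict(r=round(r_up_gb, 4), p=p_up_gb),
            upstream_bss=dict(r=round(r_up_bss, 4), p=p_up_bss),
        ),
        per_allele_roc=dict(
            n_pathogenetic=int(labels.sum()),
            n_non_pathogenetic=int((~labels).sum()),
            auc=round(allele_roc.auc, 3),
            cutoff=round(allele_roc.cutoff, 2),
            sensitivity=round(allele_roc.sensitivity, 4),
            specificity=round(allele_roc.specificity, 4),
        ),
        bss_roc=dict(n=int(len(bss)), auc=round(bss_roc.auc, 3)),
    )
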