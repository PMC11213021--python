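"""Enrichment of correlated motions inside coevolving residue groups.

Pairwise dynamic cross-correlations are mapped onto IC categories and the
resulting |DCC| distributions are contrasted with Mann-Whitney U tests, both
within one trajectory condition (each IC against pairs outside it) and
between two conditions (e.g. wild type against a dynamics-knockout mutant).

Category scheme for a retained residue pair (sequence separation > 2 by
default, so adjacent and next-nearest pairs never skew the statistics):

* ``IC_k``           — both residues belong to the same IC ``k``;
* ``no_ic``          — neither residue belongs to any IC;
* ``any_ic``         — both residues belong to ICs (same or different);
* ``not_in_same_ic`` — every pair except the same-IC ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sca import ICAssignment
from .trajectory import DCCMatrix


@dataclass
class InsertionSpec:
    """Renumbering for an insertion mutant: residues >= the site shift by offset."""

    insertion_after: int
    offset: int = 1

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("offset must be nonzero")


def renumber_for_insertion(
    residues: list[int] | np.ndarray, spec: InsertionSpec
) -> dict[int, int]:
    """Bijective old→new residue-number map accounting for an insertion.

    Residues at positions >= ``insertion_after`` shift by ``offset`` (with the
    default site 23, offset +1: position 23 becomes residue 24 and so on);
    residues before the site are unchanged.
    """
    res = sorted(int(r) for r in residues)
    if len(set(res)) != len(res):
        raise ValueError("residues must be unique")
    mapping = {
        r: (r + spec.offset if r >= spec.insertion_after else r) for r in res
    }
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("insertion renumbering produced colliding residues")
    return mapping


def renumber_dcc(dcc: DCCMatrix, spec: InsertionSpec) -> DCCMatrix:
    """Apply insertion renumbering to a DCC matrix's residue labels."""
    mapping = renumber_for_insertion(dcc.residue_numbers, spec)
    new = np.array([mapping[int(r)] for r in dcc.residue_numbers])
    return DCCMatrix(c=dcc.c, residue_numbers=new)


# ---------------------------------------------------------------------------
# pair categorisation
# ---------------------------------------------------------------------------

def categorize_pairs(
    dcc: DCCMatrix,
    ics: ICAssignment,
    min_separation: int = 2,
) -> pd.DataFrame:
    """All unordered residue pairs farther than ``min_separation`` apart.

    Separation is computed on residue numbering (apply insertion renumbering
    first for insertion mutants); pairs with separation <= ``min_separation``
    are excluded.  Each retained row carries the IC of both residues (or
    <NA>).  Raises if an IC member is absent from the DCC numbering frame.
    """
    resnums = dcc.residue_numbers
    ic_of = ics.ic_of_residue()
    missing = sorted(set(ic_of) - set(int(r) for r in resnums))
    if missing:
        raise ValueError(
            f"IC residues absent from the DCC matrix (numbering-frame "
            f"mismatch?): {missing}"
        )
    iu, ju = np.triu_indices(len(resnums), k=1)
    ri, rj = resnums[iu], resnums[ju]
    sep = np.abs(ri - rj)
    keep = sep > min_separation
    df = pd.DataFrame(
        {
            "res_i": np.minimum(ri, rj)[keep],
            "res_j": np.maximum(ri, rj)[keep],
            "separation": sep[keep],
            "dcc_value": dcc.c[iu, ju][keep],
        }
    )
    df["ic_i"] = pd.array(
        [ic_of.get(int(r)) for r in df["res_i"]], dtype="Int64"
    )
    df["ic_j"] = pd.array(
        [ic_of.get(int(r)) for r in df["res_j"]], dtype="Int64"
    )
    return df


def category_distributions(
    pairs: pd.DataFrame, n_ics: int | None = None
) -> dict[str, np.ndarray]:
    """|DCC| multisets per IC category.

    A pair with both residues in IC k contributes to ``IC_k`` and ``any_ic``;
    a pair spanning two different ICs contributes to ``any_ic`` and
    ``not_in_same_ic``; a pair with at most one IC residue contributes to
    ``not_in_same_ic``, and additionally to ``no_ic`` when neither residue
    has an IC.  Empty categories are kept (empty arrays).
    """
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    vals = np.abs(pairs["dcc_value"].to_numpy(dtype=float))
    ic_i = pairs["ic_i"].fillna(-1).to_numpy(dtype=int)
    ic_j = pairs["ic_j"].fillna(-1).to_numpy(dtype=int)
    has_i = ic_i > 0
    has_j = ic_j > 0
    same = has_i & has_j & (ic_i == ic_j)
    both = has_i & has_j
    neither = ~has_i & ~has_j

    ks = sorted({int(k) for k in ic_i[has_i]} | {int(k) for k in ic_j[has_j]})
    if n_ics is not None:
        ks = sorted(set(ks) | set(range(1, n_ics + 1)))
    dists: dict[str, np.ndarray] = {}
    for k in ks:
        dists[f"IC{k}"] = vals[same & (ic_i == k)]
    dists["no_ic"] = vals[neither]
    dists["any_ic"] = vals[both]
    dists["not_in_same_ic"] = vals[~same]
    return dists


# ---------------------------------------------------------------------------
# Mann-Whitney machinery
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    u_statistic: float
    p_value: float
    alternative: str
    n: int
    m: int
    star_label: str


def significance_label(p: float) -> str:
    """Star convention: * p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p={p} outside (0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return stars
    return "ns"


_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, alternative: str = "two_sided"
) -> TestResult:
    """Mann-Whitney U test of ``a`` against ``b``.

    ``U = #(a_i > b_j) + 0.5 #(a_i = b_j)``.  The p-value is exact (full
    enumeration) for tie-free samples with ``n*m <= 64``; otherwise it uses
    the normal approximation with midrank tie correction and continuity
    correction.  When U sits exactly at its null mean the two-sided p is 1.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    tie_free = len(np.unique(combined)) == n + m
    u = float(
        np.sum(a[:, None] > b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :])
    )
    if u == n * m / 2 and alternative == "two_sided":
        p = 1.0
    else:
        method = "exact" if (tie_free and n * m <= 64) else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative=_ALTERNATIVES[alternative], method=method
        )
        p = float(min(res.pvalue, 1.0))
    return TestResult(
        u_statistic=u,
        p_value=p,
        alternative=alternative,
        n=n,
        m=m,
        star_label=significance_label(p),
    )


# ---------------------------------------------------------------------------
# contrast batteries
# ---------------------------------------------------------------------------

def _contrast_row(name_a, name_b, a, b) -> dict:
    row = {
        "contrast": f"{name_a} vs {name_b}",
        "category_a": name_a,
        "category_b": name_b,
        "n": len(a),
        "m": len(b),
        "mean_a": float(np.mean(a)) if len(a) else np.nan,
        "mean_b": float(np.mean(b)) if len(b) else np.nan,
    }
    if len(a) == 0 or len(b) == 0:
        row.update(
            u=np.nan, p_two_sided=np.nan, p_one_sided=np.nan,
            direction="not_computable", stars="ns",
        )
        return row
    two = mann_whitney_u(a, b, "two_sided")
    direction = "greater" if row["mean_a"] >= row["mean_b"] else "less"
    one = mann_whitney_u(a, b, direction)
    row.update(
        u=two.u_statistic,
        p_two_sided=two.p_value,
        p_one_sided=one.p_value,
        direction=direction,
        stars=two.star_label,
    )
    return row


def _finalize_report(rows: list[dict]) -> pd.DataFrame:
    report = pd.DataFrame(rows)
    pvals = report["p_two_sided"].to_numpy(dtype=float)
    holm = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        holm[ok] = multipletests(pvals[ok], method="holm")[1]
    report["holm_p"] = holm
    return report


def compare_within_condition(dists: dict[str, np.ndarray]) -> pd.DataFrame:
    """Contrast battery inside one condition.

    For every IC category: IC_k vs ``not_in_same_ic`` and IC_k vs ``no_ic``;
    plus ``any_ic`` vs ``no_ic``.  Reports two-sided and one-sided p (with
    the direction of the mean difference), sample sizes, category means,
    star labels and a Holm-adjusted column.  Contrasts with an empty side
    are flagged ``not_computable``.
    """
    ic_names = sorted(
        (k for k in dists if k.startswith("IC")), key=lambda s: int(s[2:])
    )
    rows = []
    for k in ic_names:
        rows.append(_contrast_row(k, "not_in_same_ic", dists[k], dists["not_in_same_ic"]))
        rows.append(_contrast_row(k, "no_ic", dists[k], dists["no_ic"]))
    rows.append(_contrast_row("any_ic", "no_ic", dists["any_ic"], dists["no_ic"]))
    return _finalize_report(rows)


def compare_between_conditions(
    dists_a: dict[str, np.ndarray],
    dists_b: dict[str, np.ndarray],
    label_a: str = "condition_a",
    label_b: str = "condition_b",
) -> pd.DataFrame:
    """Per-category contrasts between two conditions (same category scheme)."""
    cats = [c for c in dists_a if c in dists_b]
    rows = []
    for cat in cats:
        row = _contrast_row(cat, cat, dists_a[cat], dists_b[cat])
        row["contrast"] = f"{cat}: {label_a} vs {label_b}"
        rows.append(row)
    return _finalize_report(rows)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_category_distributions(
    dists: dict[str, np.ndarray], path: str | Path, title: str = ""
) -> None:
    """Box plot of |DCC| per category (optional figure output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [k for k, v in dists.items() if len(v)]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.boxplot([dists[k] for k in names], tick_labels=names)
    ax.set_ylabel("|DCC|")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
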