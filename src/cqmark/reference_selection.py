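"""Model-based reference-miRNA stability ranking (NormFinder-style).

Candidate reference genes are ranked by a stability value that
decomposes, on the log2 (Cq/dCq) scale, each candidate's variation
into an intragroup variance and a shrunken systematic intergroup
difference.  For candidate gene i in group g with n_g samples:

1. center each sample across the candidate genes:
   ``z_igj = x_igj - mean_i x_igj`` (removes any per-sample shift);
2. per gene and group, ``m_ig = mean_j z_igj`` and ``s2_ig`` the
   unbiased variance of ``z_igj``;
3. weighted grand mean ``m_i = sum_g n_g m_ig / sum_g n_g``, raw
   intergroup difference ``d_ig = m_ig - m_i``;
4. shrink toward zero using the estimated between-group variance
   ``gamma2_i = max(0, mean_g d_ig^2 * G/(G-1) ... )``; concretely
   ``gamma2_i = max(0, (1/(G-1)) sum_g d_ig^2 - (1/G) sum_g s2_ig/n_g)``
   and ``d~_ig = d_ig * gamma2_i / (gamma2_i + s2_ig/n_g)`` (0 when
   ``gamma2_i = 0``);
5. stability ``rho_i = (1/G) sum_g ( |d~_ig| + sqrt(s2_ig/n_g) )``.

Lower rho means a more stable candidate; a gene can only score well if
it is both reproducible within groups and undifferentiated between
them.  The estimator requires at least three candidates (the centering
step needs company) and candidates detected in every sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StabilityRanking", "stability_values", "select_references"]


@dataclass
class StabilityRanking:
    """Per-candidate stability values, ascending rank 1 = most stable.

    ``table`` columns: assay_id, stability, rank, plus per-group
    intragroup variance (``var_<group>``) and shrunken intergroup
    difference (``diff_<group>``).
    """

    table: pd.DataFrame
    n_genes: int
    group_sizes: dict
    excluded: dict = field(default_factory=dict)

    def top(self, k: int) -> list:
        return self.table.nsmallest(k, "rank")["assay_id"].tolist()


def stability_values(
    matrix: pd.DataFrame,
    groups: pd.Series,
    candidates: list | None = None,
) -> StabilityRanking:
    """Rank candidate reference assays by model-based stability.

    ``matrix`` is samples x assays on a log2 scale (raw or calibrated
    Cq, or dCq — the centering step makes the choice immaterial up to
    per-sample constants); ``groups`` maps sample -> group label.
    Candidates with any missing (undetected) value are excluded with a
    warning.  Ties in stability break lexicographically on assay id.
    """
    if candidates is None:
        candidates = list(matrix.columns)
    candidates = [c for c in candidates if c in matrix.columns]
    groups = pd.Series(groups).reindex(matrix.index)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")

    sub = matrix[candidates]
    excluded = {
        c: "undetected in some samples" for c in sub.columns[sub.isna().any()]
    }
    if excluded:
        warnings.warn(
            f"candidates excluded (not detected in all samples): "
            f"{sorted(excluded)}",
            stacklevel=2,
        )
    kept = [c for c in candidates if c not in excluded]
    if len(kept) < 3:
        raise ValueError(
            f"need at least 3 fully detected candidates, have {len(kept)}"
        )
    sub = sub[kept]

    labels = sorted(groups.unique())
    G = len(labels)
    if G < 2:
        raise ValueError("need at least 2 groups")
    n_g = {g: int((groups == g).sum()) for g in labels}
    if min(n_g.values()) < 2:
        raise ValueError("need at least 2 samples per group")

    # (1) remove per-sample level across candidates
    z = sub.sub(sub.mean(axis=1), axis=0)

    m = np.empty((len(kept), G))
    s2 = np.empty((len(kept), G))
    for gi, g in enumerate(labels):
        zg = z.loc[groups[groups == g].index]
        m[:, gi] = zg.mean(axis=0).to_numpy()
        s2[:, gi] = zg.var(axis=0, ddof=1).to_numpy()

    n_vec = np.array([n_g[g] for g in labels], float)
    grand = (m * n_vec).sum(axis=1) / n_vec.sum()
    d = m - grand[:, None]

    sem2 = s2 / n_vec[None, :]  # s2_ig / n_g
    gamma2 = np.maximum(
        0.0, (d**2).sum(axis=1) / (G - 1) - sem2.sum(axis=1) / G
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(
            gamma2[:, None] > 0, gamma2[:, None] / (gamma2[:, None] + sem2), 0.0
        )
    d_tilde = d * shrink

    rho = (np.abs(d_tilde) + np.sqrt(sem2)).mean(axis=1)

    tab = pd.DataFrame({"assay_id": kept, "stability": rho})
    for gi, g in enumerate(labels):
        tab[f"var_{g}"] = s2[:, gi]
        tab[f"diff_{g}"] = d_tilde[:, gi]
    tab = tab.sort_values(["stability", "assay_id"], kind="mergesort").reset_index(
        drop=True
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    return StabilityRanking(
        table=tab, n_genes=len(kept), group_sizes=n_g, excluded=excluded
    )


@dataclass
class SelectedReferences:
    assays: list
    stability: dict
    group_diff_p: float | None   # t-test on the chosen assays' mean raw Cq
    per_assay_p: dict
    warning: str | None = None


def select_references(
    ranking: StabilityRanking,
    k: int = 2,
    stability_cutoff: float | None = None,
    cq_matrix: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
    equal_var: bool = False,
) -> SelectedReferences:
    """Choose the top-k most stable candidates (optionally cutoff-gated).

    When a raw (or calibrated) Cq matrix and group labels are supplied,
    the choice is double-checked with a two-sample t-test on the chosen
    assays' mean Cq — a sound reference pair shows no group difference.
    Fewer than k survivors of the cutoff is a warning, not an error.
    """
    if ranking.table.empty:
        raise ValueError("empty stability ranking")
    tab = ranking.table
    if stability_cutoff is not None:
        tab = tab[tab["stability"] <= stability_cutoff]
    chosen = tab.nsmallest(k, "rank")["assay_id"].tolist()
    warning = None
    if len(chosen) < k:
        warning = (
            f"only {len(chosen)} candidate(s) meet stability cutoff "
            f"{stability_cutoff}; requested {k}"
        )

    group_p = None
    per_assay_p: dict = {}
    if chosen and cq_matrix is not None and groups is not None:
        groups = pd.Series(groups).reindex(cq_matrix.index)
        labels = sorted(groups.dropna().unique())
        if len(labels) == 2:
            a_idx = groups == labels[0]
            b_idx = groups == labels[1]
            mean_cq = cq_matrix[chosen].mean(axis=1)
            group_p = float(
                stats.ttest_ind(
                    mean_cq[a_idx].dropna(),
                    mean_cq[b_idx].dropna(),
                    equal_var=equal_var,
                ).pvalue
            )
            for a in chosen:
                per_assay_p[a] = float(
                    stats.ttest_ind(
                        cq_matrix.loc[a_idx, a].dropna(),
                        cq_matrix.loc[b_idx, a].dropna(),
                        equal_var=equal_var,
                    ).pvalue
                )
    stability = dict(
        zip(ranking.table["assay_id"], ranking.table["stability"])
    )
    return SelectedReferences(
        assays=chosen,
        stability={a: stability[a] for a in chosen},
        group_diff_p=group_p,
        per_assay_p=per_assay_p,
        warning=warning,
    )
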