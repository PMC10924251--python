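"""Relative fitness scoring for selection-based propagation assays.

The fitness statistic is a log-ratio enrichment score. For a variant v with
input (pre-selection) count v_in and output (post-selection) count v_out,
and a designated reference with counts r_in, r_out:

    F(v) = log10(v_out / v_in) − log10(r_out / r_in)

F is in log10 units: F = 0 means the variant propagates at the reference
rate, F = −1 means 10-fold slower, F = −2 means 100-fold slower, and
10**F is the fold change in propagation rate. A pseudocount is invoked only
when a raw count is zero, and the affected score is flagged LOW_COUNT.

The synonymous (silent) codon variants of the wild-type sequence propagate
at the wild-type rate by construction, so the spread of their F values
measures pure assay noise; the neutrality band is their mean ± 3 SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

LOW_COUNT_FLAG = "LOW_COUNT"
LN10 = math.log(10.0)


class CountTableError(ValueError):
    """Invalid count table (missing reference, negative counts, ...)."""


@dataclass(frozen=True)
class SynonymousStats:
    """Summary of the synonymous-variant fitness distribution (the assay null)."""

    n: int
    mean_F: float
    sd_F: float
    n_sd: float = 3.0

    @property
    def band_lo(self) -> float:
        return self.mean_F - self.n_sd * self.sd_F

    @property
    def band_hi(self) -> float:
        return self.mean_F + self.n_sd * self.sd_F

    @property
    def band_fold(self) -> float:
        """Half-width of the neutrality band expressed as a fold change."""
        return 10.0 ** (self.n_sd * self.sd_F)


def fitness_score(
    v_in: float, v_out: float, r_in: float, r_out: float, pseudocount: float = 0.5
) -> tuple[float, bool]:
    """Relative fitness F of a variant versus the reference.

    Returns ``(F, low_count)`` where ``low_count`` is True when any raw
    count was zero and the pseudocount was applied (to every count of that
    row pair, keeping the score anti-symmetric).
    """
    for c in (v_in, v_out, r_in, r_out):
        if c < 0:
            raise CountTableError(f"negative count {c}")
    low = min(v_in, v_out, r_in, r_out) == 0
    c = pseudocount if low else 0.0
    if v_in + c <= 0 or r_in + c <= 0 or r_out + c <= 0:
        raise CountTableError("counts remain non-positive after pseudocount")
    F = math.log10((v_out + c) / (v_in + c)) - math.log10((r_out + c) / (r_in + c))
    return F, low


def fold_change(F: float) -> float:
    """Fold change in propagation rate implied by fitness score F: 10**F."""
    return 10.0**F


def fitness_se(v_in: float, v_out: float, r_in: float, r_out: float) -> float:
    """Delta-method standard error of F under Poisson counting noise.

    se = (1/ln 10) * sqrt(1/v_in + 1/v_out + 1/r_in + 1/r_out); undefined
    (NaN) when any count is zero.
    """
    if min(v_in, v_out, r_in, r_out) <= 0:
        return float("nan")
    return math.sqrt(1 / v_in + 1 / v_out + 1 / r_in + 1 / r_out) / LN10


def fitness_table(
    counts: pd.DataFrame, reference: str, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Score every variant of a count table against ``reference``.

    ``counts`` needs columns ``variant_name``, ``input_count``,
    ``output_count`` and may carry a ``replicate`` column; with replicates,
    per-replicate scores are combined by inverse-variance weighting (simple
    mean if the weights are undefined). Returns a table with columns
    ``variant_name``, ``F``, ``se``, ``fold``, ``flags``; the reference row
    scores exactly 0.
    """
    required = {"variant_name", "input_count", "output_count"}
    missing = required - set(counts.columns)
    if missing:
        raise CountTableError(f"count table missing columns {sorted(missing)}")
    if (counts["input_count"] < 0).any() or (counts["output_count"] < 0).any():
        raise CountTableError("negative counts in table")

    if "replicate" in counts.columns:
        groups = list(counts.groupby("replicate", sort=True))
    else:
        groups = [(0, counts)]

    per_rep: list[pd.DataFrame] = []
    for rep, tab in groups:
        ref_rows = tab.loc[tab["variant_name"] == reference]
        if len(ref_rows) != 1:
            raise CountTableError(
                f"replicate {rep}: expected exactly one reference row "
                f"{reference!r}, found {len(ref_rows)}"
            )
        r_in = float(ref_rows["input_count"].iloc[0])
        r_out = float(ref_rows["output_count"].iloc[0])
        if r_in == 0 or r_out == 0:
            if r_in + pseudocount <= 0 or r_out + pseudocount <= 0:
                raise CountTableError(f"replicate {rep}: unusable reference counts")
        rows = []
        for _, row in tab.iterrows():
            F, low = fitness_score(
                row["input_count"], row["output_count"], r_in, r_out, pseudocount
            )
            se = fitness_se(row["input_count"], row["output_count"], r_in, r_out)
            rows.append(
                {
                    "variant_name": row["variant_name"],
                    "replicate": rep,
                    "F": F,
                    "se": se,
                    "low": low,
                }
            )
        per_rep.append(pd.DataFrame(rows))

    long = pd.concat(per_rep, ignore_index=True)

    def _combine(g: pd.DataFrame) -> pd.Series:
        F = g["F"].to_numpy(float)
        se = g["se"].to_numpy(float)
        if len(F) == 1:
            F_hat, se_hat = F[0], se[0]
        elif np.isfinite(se).all() and (se > 0).all():
            w = 1.0 / se**2
            F_hat = float(np.sum(w * F) / np.sum(w))
            se_hat = float(1.0 / math.sqrt(np.sum(w)))
        else:
            F_hat, se_hat = float(np.mean(F)), float("nan")
        return pd.Series(
            {
                "F": F_hat,
                "se": se_hat,
                "fold": 10.0**F_hat,
                "flags": LOW_COUNT_FLAG if g["low"].any() else "",
            }
        )

    out = (
        long.groupby("variant_name", sort=False)
        .apply(_combine, include_groups=False)
        .reset_index()
    )
    return out


def rereference(table: pd.DataFrame, new_reference: str) -> pd.DataFrame:
    """Re-express a fitness table relative to another variant in the table.

    F_new(v) = F_old(v) − F_old(new_reference); pairwise differences are
    preserved and the new reference scores exactly 0. Standard errors are
    left as computed against the original reference counts.
    """
    hits = table.loc[table["variant_name"] == new_reference, "F"]
    if hits.empty:
        raise KeyError(f"reference {new_reference!r} not present in fitness table")
    shift = float(hits.iloc[0])
    out = table.copy()
    out["F"] = out["F"] - shift
    out["fold"] = 10.0 ** out["F"]
    return out


def synonymous_stats(
    table: pd.DataFrame, synonymous_names: list[str], n_sd: float = 3.0
) -> SynonymousStats:
    """Mean/SD of the synonymous fitness distribution and the neutrality band.

    Each synonymous codon variant is an independent null observation; at
    least two with finite F are required for a sample SD.
    """
    sub = table.loc[table["variant_name"].isin(set(synonymous_names)), "F"]
    sub = sub[np.isfinite(sub)]
    if len(sub) < 2:
        raise CountTableError(
            f"need >=2 scored synonymous variants for the null, got {len(sub)}"
        )
    return SynonymousStats(
        n=int(len(sub)), mean_F=float(sub.mean()), sd_F=float(sub.std(ddof=1)), n_sd=n_sd
    )
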