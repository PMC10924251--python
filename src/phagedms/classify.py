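"""Fitness-effect classification: DFE, neutrality, benefit, conditional neutrality.

Definitions used throughout (all on log10 fitness scores F):

- *neutral*: F inside the closed band mean ± 3 SD of the synonymous-variant
  fitness distribution of the same experiment;
- *beneficial*: at least a ``threshold_fold`` (default 10-fold) increase,
  i.e. F >= log10(threshold_fold), boundary included;
- *conditionally neutral*: neutral in the first genetic background and
  beneficial in the second;
- *gain-of-function position*: a residue position with at least
  ``min_mutations`` beneficial substitutions.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pandas as pd

from .codons import AMINO_ACIDS
from .fitness import SynonymousStats

_POS_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


def _parse_name(name: str) -> tuple[str, int, str] | None:
    m = _POS_RE.match(name)
    if not m:
        return None
    return m.group(1), int(m.group(2)), m.group(3)


def dfe(table: pd.DataFrame, bins: int | np.ndarray = 30) -> pd.DataFrame:
    """Histogram of the distribution of fitness effects.

    Returns a frame with ``bin_lo``, ``bin_hi``, ``count``; counts sum to
    the number of scored (finite-F) variants.
    """
    F = table["F"].to_numpy(float)
    F = F[np.isfinite(F)]
    if F.size == 0:
        raise ValueError("no scored variants for a DFE")
    counts, edges = np.histogram(F, bins=bins)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})


def call_beneficial(table: pd.DataFrame, threshold_fold: float = 10.0,
                    strict: bool = False) -> set[str]:
    """Variants with at least a ``threshold_fold`` fitness increase.

    The boundary F == log10(threshold_fold) is included unless ``strict``.
    """
    thr = math.log10(threshold_fold)
    F = table["F"]
    mask = F > thr if strict else F >= thr
    return set(table.loc[mask, "variant_name"])


def call_neutral(table: pd.DataFrame, syn_stats: SynonymousStats) -> set[str]:
    """Variants inside the closed synonymous neutrality band."""
    mask = (table["F"] >= syn_stats.band_lo) & (table["F"] <= syn_stats.band_hi)
    return set(table.loc[mask, "variant_name"])


def conditional_neutrality(
    table_bg1: pd.DataFrame,
    syn_stats_bg1: SynonymousStats,
    table_bg2: pd.DataFrame,
    threshold_fold: float = 10.0,
) -> pd.DataFrame:
    """Joint classification of variants scored in two genetic backgrounds.

    Background 1 supplies the neutrality call (its own synonymous band);
    background 2 supplies the beneficial call. Variants present in only one
    table are excluded. Returns one row per shared variant with boolean
    columns ``neutral_in_1``, ``beneficial_in_2``, ``conditionally_neutral``.
    """
    f1 = table_bg1.set_index("variant_name")["F"]
    f2 = table_bg2.set_index("variant_name")["F"]
    shared = f1.index.intersection(f2.index)
    neutral = call_neutral(table_bg1, syn_stats_bg1)
    beneficial = call_beneficial(table_bg2, threshold_fold)
    rows = []
    for v in shared:
        n1, b2 = v in neutral, v in beneficial
        rows.append(
            {
                "variant_name": v,
                "F_bg1": float(f1[v]),
                "F_bg2": float(f2[v]),
                "neutral_in_1": n1,
                "beneficial_in_2": b2,
                "conditionally_neutral": n1 and b2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_name", "F_bg1", "F_bg2",
            "neutral_in_1", "beneficial_in_2", "conditionally_neutral",
        ],
    )


def gain_of_function_positions(
    table: pd.DataFrame,
    threshold_fold: float = 10.0,
    min_mutations: int = 2,
    strict: bool = False,
) -> pd.DataFrame:
    """Residue positions with >= ``min_mutations`` beneficial substitutions.

    Returns one row per qualifying position: ``position``, ``wt_aa``,
    ``n_beneficial``, ``beneficial_mutations`` (comma-joined names).
    """
    beneficial = call_beneficial(table, threshold_fold, strict=strict)
    per_pos: dict[int, dict] = {}
    for name in table["variant_name"]:
        parsed = _parse_name(name)
        if parsed is None:
            continue
        wt, pos, mut = parsed
        rec = per_pos.setdefault(pos, {"wt_aa": wt, "hits": []})
        if mut != wt and name in beneficial:
            rec["hits"].append(name)
    rows = [
        {
            "position": pos,
            "wt_aa": rec["wt_aa"],
            "n_beneficial": len(rec["hits"]),
            "beneficial_mutations": ",".join(sorted(rec["hits"])),
        }
        for pos, rec in sorted(per_pos.items())
        if len(rec["hits"]) >= min_mutations
    ]
    return pd.DataFrame(
        rows, columns=["position", "wt_aa", "n_beneficial", "beneficial_mutations"]
    )


WT_SENTINEL = "WT"


def heatmap_matrix(
    table: pd.DataFrame, positions: range | list[int] | None = None
) -> pd.DataFrame:
    """Positions x 20 amino-acid matrix of F for heatmap display.

    Rows are residue positions, columns the amino acids in alphabetical
    one-letter order. Missing measurements are NaN; wild-type identity
    cells carry 0 and are listed separately in the frame's ``attrs["wt_aa"]``
    map so they can be marked distinctly from a measured F = 0.
    """
    parsed = [(_parse_name(n), F) for n, F in zip(table["variant_name"], table["F"])]
    parsed = [(p, F) for p, F in parsed if p is not None]
    if positions is None:
        positions = sorted({p[1] for p, _ in parsed})
    mat = pd.DataFrame(
        np.nan, index=list(positions), columns=list(AMINO_ACIDS), dtype=float
    )
    wt_map: dict[int, str] = {}
    for (wt, pos, mut), F in parsed:
        if pos not in mat.index:
            continue
        wt_map[pos] = wt
        if mut in mat.columns:
            mat.loc[pos, mut] = F
    for pos, wt in wt_map.items():
        if wt in mat.columns and pd.isna(mat.loc[pos, wt]):
            mat.loc[pos, wt] = 0.0
    mat.index.name = "position"
    mat.attrs["wt_aa"] = wt_map
    return mat


def heatmap_to_long(mat: pd.DataFrame) -> pd.DataFrame:
    """Serialize a heatmap matrix to a long (position, aa, F) table."""
    # value_name "F" would collide with the phenylalanine column during melt
    long = mat.reset_index().melt(
        id_vars="position", var_name="mut_aa", value_name="_F"
    ).rename(columns={"_F": "F"})
    return long.dropna(subset=["F"]).reset_index(drop=True)


def long_to_heatmap(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`heatmap_to_long` (round-trips measured cells)."""
    mat = pd.DataFrame(
        np.nan,
        index=sorted(long["position"].unique()),
        columns=list(AMINO_ACIDS),
        dtype=float,
    )
    for _, row in long.iterrows():
        mat.loc[row["position"], row["mut_aa"]] = row["F"]
    mat.index.name = "position"
    return mat
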