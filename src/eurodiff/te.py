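"""Transposable-element differentiation from presence/absence calls.

TE insertions called per strain (present/absent/missing, T-lex style) are
treated as biallelic loci with homozygous genotypes (inbred lines:
present = 1/1, absent = 0/0).  TEs are classified before testing:
``undetermined`` when a population's missing-call fraction is too high,
``fixed_both`` when present in every called strain of both populations,
``low_freq_both`` when below the frequency threshold in both, and
``testable`` otherwise.  Testable TEs get the same Weir & Cockerham theta
as SNPs and are called candidates against the SNP-derived per-arm critical
values, so the TE test is calibrated on the genome-wide SNP F_ST
distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from eurodiff.fst import site_fst_wc, tier_label

__all__ = ["load_te_calls", "classify_tes", "te_fst", "te_candidates"]

CALL_CODE = {"P": 2, "A": 0, "-": -1}


def load_te_calls(path, strains: list[str] | None = None) -> pd.DataFrame:
    """Read a T-lex-style TE table: te_id, family, arm, pos, one column per strain.

    Calls must be 'P', 'A' or '-'.  With ``strains`` given, the table's
    strain columns must match that cohort exactly.  Duplicate TE ids and
    unknown call symbols are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["te_id", "family", "arm", "pos"]
    call_cols = [c for c in df.columns if c not in meta_cols]
    if strains is not None:
        unknown = [c for c in call_cols if c not in strains]
        absent = [s for s in strains if s not in call_cols]
        if unknown or absent:
            raise ValueError(
                f"strain columns do not match cohort (unknown={unknown}, absent={absent})"
            )
        call_cols = list(strains)
    if df["te_id"].duplicated().any():
        dup = df.loc[df["te_id"].duplicated(), "te_id"].iloc[0]
        raise ValueError(f"duplicate te_id {dup!r}")
    for c in call_cols:
        bad = ~df[c].isin(CALL_CODE)
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"unknown call symbol {row[c]!r} for {row['te_id']} "
                f"({row['arm']}:{row['pos']}, strain {c})"
            )
    df["pos"] = df["pos"].astype(int)
    return df[meta_cols + call_cols]


def _call_matrix(te_table: pd.DataFrame, strains: list[str]) -> np.ndarray:
    return np.vstack(
        [te_table[s].map(CALL_CODE).to_numpy(dtype=np.int8) for s in strains]
    ).T


def classify_tes(
    te_table: pd.DataFrame,
    populations: dict[str, str],
    pop_a: str,
    pop_b: str,
    maf_min: float = 0.05,
    max_missing: float = 0.30,
) -> pd.DataFrame:
    """Classify every TE and attach per-population frequencies.

    Order of the rules: ``undetermined`` if either population's missing
    fraction exceeds ``max_missing``; else ``fixed_both`` if the presence
    frequency among called strains is exactly 1 in both populations; else
    ``low_freq_both`` if below ``maf_min`` in both; else ``testable``.
    """
    strains_a = [s for s, p in populations.items() if p == pop_a and s in te_table.columns]
    strains_b = [s for s, p in populations.items() if p == pop_b and s in te_table.columns]
    if not strains_a or not strains_b:
        raise ValueError("both populations need strain columns in the TE table")
    out = te_table[["te_id", "family", "arm", "pos"]].copy()
    for label, strains in ((pop_a, strains_a), (pop_b, strains_b)):
        calls = _call_matrix(te_table, strains)
        called = calls >= 0
        n_called = called.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(calls == 2, 1, 0).sum(axis=1) / np.where(
                n_called == 0, np.nan, n_called
            )
        out[f"freq_{label}"] = freq
        out[f"missing_{label}"] = 1 - called.mean(axis=1)

    fa, fb = out[f"freq_{pop_a}"], out[f"freq_{pop_b}"]
    undet = (
        (out[f"missing_{pop_a}"] > max_missing)
        | (out[f"missing_{pop_b}"] > max_missing)
        | fa.isna()
        | fb.isna()
    )
    fixed = (fa == 1) & (fb == 1)
    low = (fa < maf_min) & (fb < maf_min)
    out["classification"] = "testable"
    out.loc[low, "classification"] = "low_freq_both"
    out.loc[fixed, "classification"] = "fixed_both"
    out.loc[undet, "classification"] = "undetermined"
    return out


def te_fst(
    te_table: pd.DataFrame,
    classified: pd.DataFrame,
    populations: dict[str, str],
    pop_a: str,
    pop_b: str,
) -> pd.DataFrame:
    """Weir & Cockerham theta for every testable TE.

    Presence/absence is encoded as homozygous diploid genotypes and fed to
    the same component computation as SNPs.  A TE whose encoding leaves a
    population with no called strain is reclassified ``undetermined``.
    """
    strains_a = [s for s, p in populations.items() if p == pop_a and s in te_table.columns]
    strains_b = [s for s, p in populations.items() if p == pop_b and s in te_table.columns]
    out = classified.copy()
    out["fst"] = np.nan
    testable = out["classification"] == "testable"
    if not testable.any():
        return out
    tbl = te_table.set_index("te_id").loc[out.loc[testable, "te_id"]]
    ga = _call_matrix(tbl.reset_index(), strains_a)
    gb = _call_matrix(tbl.reset_index(), strains_b)
    _, theta = site_fst_wc(ga, gb)
    idx = out.index[testable]
    out.loc[idx, "fst"] = theta
    empty = ((ga >= 0).sum(axis=1) == 0) | ((gb >= 0).sum(axis=1) == 0)
    out.loc[idx[empty], "classification"] = "undetermined"
    out.loc[idx[empty], "fst"] = np.nan
    return out


def te_candidates(
    te_scored: pd.DataFrame,
    snp_thresholds: pd.DataFrame,
    tails: tuple[float, ...] = (0.05, 0.01, 0.005),
) -> pd.DataFrame:
    """Tier calls for testable TEs against SNP-derived per-arm critical values.

    A TE is a tier-t candidate iff theta >= the tier-t critical F_ST of its
    arm's SNP distribution.  TEs on arms lacking a SNP threshold are
    reported with NaN tier columns (skipped, warning left to the caller).
    The direction column says which population carries the insertion at
    higher frequency.
    """
    tails = tuple(sorted(tails, reverse=True))
    out = te_scored.copy()
    thr = snp_thresholds.set_index(["arm", "tail"])["critical_fst"]
    freq_cols = [c for c in out.columns if c.startswith("freq_")]
    pa, pb = freq_cols[0][5:], freq_cols[1][5:]
    out["direction"] = np.where(
        out[freq_cols[0]] > out[freq_cols[1]], pa, np.where(
            out[freq_cols[0]] < out[freq_cols[1]], pb, "equal"
        )
    )
    out.loc[out["classification"] != "testable", "direction"] = ""
    for tail in tails:
        col = f"candidate_{tier_label(tail)}"
        vals = []
        for _, row in out.iterrows():
            if row["classification"] != "testable" or not np.isfinite(row["fst"]):
                vals.append(False)
                continue
            key = (row["arm"], tail)
            if key not in thr.index:
                vals.append(None)
                continue
            vals.append(bool(row["fst"] >= thr[key]))
        out[col] = vals
    return out
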