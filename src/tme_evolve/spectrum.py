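"""Substitution-spectrum summarisation of variant tables.

Two channel schemes are supported:

* **12-class** — the literal ``ref>alt`` substitution (4 x 3 = 12 channels),
  without strand collapse.  This is the scheme used for coarse
  timepoint-level spectrum plots, where e.g. carcinogen (urethane)-induced
  tumors show characteristic A>G and A>T transitions.
* **96-class** — the COSMIC trinucleotide catalog: substitutions are
  expressed with a pyrimidine (C or T) reference by reverse-complementing
  purine-reference variants together with their 3-mer context, giving 6
  substitution types x 16 flanking contexts = 96 channels named like
  ``A[C>T]G``.

A variant row carries its own trinucleotide ``CONTEXT`` (upper-case, variant
base in the middle, 1-based center position), so no reference genome is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "channel_names",
    "classify_substitution",
    "spectrum_matrix",
    "SpectrumResult",
    "collapse_96_to_6",
    "read_variants",
    "write_variants",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = {"C", "T"}


def channel_names(scheme: str) -> list[str]:
    """Ordered channel names for a scheme ("12" or "96")."""
    scheme = str(scheme)
    if scheme == "12":
        return [f"{r}>{a}" for r in _BASES for a in _BASES if a != r]
    if scheme == "96":
        names = []
        for ref in ("C", "T"):
            for alt in _BASES:
                if alt == ref:
                    continue
                for five in _BASES:
                    for three in _BASES:
                        names.append(f"{five}[{ref}>{alt}]{three}")
        return names
    raise ValueError(f"scheme must be '12' or '96', got {scheme!r}")


def _validate_row(ref: str, alt: str, context: str) -> None:
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"invalid bases ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r}); not a substitution")
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ValueError(f"context must be a 3-mer over ACGT, got {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} does not match ref {ref!r}")


def classify_substitution(ref: str, alt: str, context: str, scheme: str = "96") -> str:
    """Map a single substitution to its spectrum channel.

    12-class: the literal ``ref>alt``.  96-class: purine-reference variants
    are reverse-complemented (ref, alt, and context) before naming, so a
    variant and its reverse complement land in the same channel.
    """
    ref, alt, context = str(ref).upper(), str(alt).upper(), str(context).upper()
    _validate_row(ref, alt, context)
    scheme = str(scheme)
    if scheme == "12":
        return f"{ref}>{alt}"
    if scheme == "96":
        if ref not in _PYRIMIDINES:
            ref, alt = _COMP[ref], _COMP[alt]
            context = "".join(_COMP[b] for b in reversed(context))
        return f"{context[0]}[{ref}>{alt}]{context[2]}"
    raise ValueError(f"scheme must be '12' or '96', got {scheme!r}")


@dataclass
class SpectrumResult:
    """Per-sample substitution counts and proportions over a channel scheme."""

    scheme: str
    counts: pd.DataFrame       # sample x channel integer counts
    proportions: pd.DataFrame  # counts / per-sample totals
    pooled: pd.Series          # pooled proportions over all samples
    invalid_rows: pd.DataFrame # rows rejected by validation (empty if none)


def spectrum_matrix(
    variants: pd.DataFrame, scheme: str = "96", strict: bool = False
) -> SpectrumResult:
    """Count substitutions per sample per channel.

    ``variants`` needs columns SAMPLE, REF, ALT, CONTEXT.  Invalid rows are
    collected and reported (or raise if ``strict``); valid rows are still
    counted.  Per-sample channel sums equal the sample's valid SNV count.
    """
    if variants.empty:
        raise ValueError("variant table is empty")
    channels = channel_names(scheme)
    assigned = []
    bad_idx = []
    for idx, row in variants.iterrows():
        try:
            assigned.append(classify_substitution(row["REF"], row["ALT"], row["CONTEXT"], scheme))
        except ValueError as err:
            if strict:
                raise ValueError(f"row {idx}: {err}") from err
            bad_idx.append(idx)
            assigned.append(None)
    ch = pd.Series(assigned, index=variants.index)
    ok = ch.notna()
    counts = (
        pd.crosstab(variants.loc[ok, "SAMPLE"], ch[ok])
        .reindex(columns=channels, fill_value=0)
        .astype(int)
    )
    counts.index.name = "sample"
    counts.columns.name = "channel"
    totals = counts.sum(axis=1)
    proportions = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    pooled_counts = counts.sum(axis=0)
    pooled = pooled_counts / max(1, pooled_counts.sum())
    return SpectrumResult(
        scheme=str(scheme),
        counts=counts,
        proportions=proportions,
        pooled=pooled,
        invalid_rows=variants.loc[bad_idx],
    )


def collapse_96_to_6(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum a 96-class count matrix over flanking bases to the 6 pyrimidine classes."""
    subs = [c.split("[")[1].split("]")[0] for c in counts.columns]
    out = counts.T.groupby(subs).sum().T
    order = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    return out[[c for c in order if c in out.columns]]


def read_variants(path) -> pd.DataFrame:
    """Read a variant TSV with VCF-like columns plus CONTEXT."""
    return pd.read_csv(path, sep="\t", dtype={"CHROM": str})


def write_variants(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)
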