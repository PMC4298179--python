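"""Typing of cosmopolitan chromosomal inversions from marker SNPs.

Each inversion (e.g. In(2L)t, In(3R)Payne) is described by a list of
inversion-specific marker SNPs — sites whose inverted-arrangement allele
distinguishes carriers.  A haplotype is typed as a carrier when, among its
non-missing markers, the fraction bearing the inverted allele reaches a
threshold (default 0.8; empirically carriers and non-carriers separate
cleanly, so the threshold only guards degenerate inputs).  Haplotypes with
too few called markers stay untyped and leave the frequency denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import HaplotypeMatrix

__all__ = ["type_inversions", "inversion_frequency_change", "read_markers"]


def read_markers(path) -> pd.DataFrame:
    """Marker TSV with columns inversion, chrom, pos, inverted_allele."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = {"inversion", "chrom", "pos", "inverted_allele"}
    if not req.issubset(df.columns):
        raise ValueError(f"marker file needs columns {sorted(req)}")
    return df


def type_inversions(matrix: HaplotypeMatrix, markers: pd.DataFrame,
                    carrier_threshold: float = 0.8,
                    min_called: int = 10) -> pd.DataFrame:
    """Carrier calls and frequencies per inversion.

    Returns one row per inversion with the carrier haplotype ids, the number
    of carriers, the number of typed haplotypes and the carrier frequency
    (rounded to 2 decimals, the reporting convention for these tables).
    """
    site_idx = {(c, p): i for i, (c, p) in
                enumerate(zip(matrix.sites["chrom"], matrix.sites["pos"]))}
    rows = []
    for inv, grp in markers.groupby("inversion", sort=False):
        cols, alleles = [], []
        for _, m in grp.iterrows():
            i = site_idx.get((m["chrom"], m["pos"]))
            if i is not None:
                cols.append(i)
                alleles.append(m["inverted_allele"])
        if not cols:
            raise ValueError(f"no markers of {inv} found in the site table")
        calls = matrix.calls[:, cols]
        alleles = np.asarray(alleles, dtype="<U1")
        called = calls != "N"
        n_called = called.sum(axis=1)
        inverted = (calls == alleles[None, :]) & called
        with np.errstate(invalid="ignore"):
            frac = np.where(n_called > 0, inverted.sum(axis=1) / n_called, 0.0)
        typed = n_called >= min(min_called, len(cols))
        carrier = typed & (frac >= carrier_threshold)
        n_typed = int(typed.sum())
        freq = carrier.sum() / n_typed if n_typed else np.nan
        rows.append({
            "inversion": inv,
            "carriers": [h for h, c in zip(matrix.ids, carrier) if c],
            "n_carriers": int(carrier.sum()),
            "n_typed": n_typed,
            "frequency": round(float(freq), 2),
        })
    return pd.DataFrame(rows)


def inversion_frequency_change(base: HaplotypeMatrix,
                               evolved: HaplotypeMatrix,
                               markers: pd.DataFrame,
                               carrier_threshold: float = 0.8,
                               min_called: int = 10) -> pd.DataFrame:
    """Base and evolved inversion frequencies plus their change.

    The change is computed from the 2-dp rounded frequencies, matching how
    such tables are conventionally reported.
    """
    b = type_inversions(base, markers, carrier_threshold, min_called)
    e = type_inversions(evolved, markers, carrier_threshold, min_called)
    out = b[["inversion", "carriers", "n_carriers", "frequency"]].rename(
        columns={"carriers": "base_carriers", "n_carriers": "n_base_carriers",
                 "frequency": "base_frequency"})
    out = out.merge(
        e[["inversion", "carriers", "n_carriers", "frequency"]].rename(
            columns={"carriers": "evolved_carriers",
                     "n_carriers": "n_evolved_carriers",
                     "frequency": "evolved_frequency"}),
        on="inversion")
    out["change"] = (out["evolved_frequency"] - out["base_frequency"]).round(2)
    return out
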