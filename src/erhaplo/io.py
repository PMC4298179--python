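"""Interchange formats and coordinate machinery for E&R analyses.

Everything downstream works on four in-memory containers:

* :class:`HaplotypeMatrix` — phased allele calls (A/C/G/T, N = missing) for a
  set of haplotypes over a shared site table.
* :class:`PoolCounts` — per-site A:T:C:G:N:del read counts for a set of
  Pool-Seq samples (PoPoolation2 "sync" dialect) together with the
  replicate/generation design of the experiment.
* :class:`RecombMap` — a piecewise-constant cM/Mb map on non-overlapping
  physical windows, used to convert physical spans to genetic distances.
* plain :class:`pandas.DataFrame` interval tables from BED / GFF3.

Coordinates are 1-based inclusive everywhere internally (the Drosophila
genome-browser convention); BED input is converted on read.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
#: column order of a sync count field
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: indices of the A/T/C/G columns within a sync count field
_ACGT_IN_SYNC = (0, 1, 2, 3)

__all__ = [
    "NUCLEOTIDES",
    "SYNC_ALLELES",
    "SyncParseError",
    "DesignError",
    "ValidationError",
    "HaplotypeMatrix",
    "PoolCounts",
    "RecombMap",
    "read_sync",
    "write_sync",
    "read_design",
    "read_haplotypes",
    "write_haplotypes",
    "read_recomb_map",
    "read_bed",
    "read_gff",
    "read_intervals",
]


class SyncParseError(ValueError):
    """A sync line could not be parsed; the message names the offending line."""


class DesignError(ValueError):
    """Sample design inconsistent with the sync file (e.g. column mismatch)."""


class ValidationError(ValueError):
    """An input file violates a container invariant (ordering, alleles ...)."""


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "pos"}
    if not required.issubset(sites.columns):
        raise ValidationError(f"site table needs columns {sorted(required)}")
    sites = sites.reset_index(drop=True)
    if (sites["pos"] < 1).any():
        raise ValidationError("positions must be 1-based (>= 1)")
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValidationError(
                f"positions not strictly increasing on chromosome {chrom}"
            )
    return sites


# ---------------------------------------------------------------------------
# HaplotypeMatrix
# ---------------------------------------------------------------------------


class HaplotypeMatrix:
    """Per-haplotype allele calls over a shared site table.

    Parameters
    ----------
    ids
        Haplotype labels (e.g. ``b1``–``b29`` for founder haplotypes).
    calls
        Array of shape ``(n_haplotypes, n_sites)`` with values in
        ``{A, C, G, T, N}``; ``N`` marks a site not called in that haplotype.
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based) and optionally
        ``ref`` (reference-strain allele).
    """

    def __init__(self, ids: Sequence[str], calls: np.ndarray, sites: pd.DataFrame):
        calls = np.asarray(calls, dtype="<U1")
        if calls.ndim != 2:
            raise ValidationError("calls must be a 2-D haplotypes x sites array")
        if calls.shape[0] != len(ids):
            raise ValidationError("number of ids does not match calls rows")
        sites = _check_sites(sites)
        if calls.shape[1] != len(sites):
            raise ValidationError("number of sites does not match calls columns")
        bad = ~np.isin(calls, list(NUCLEOTIDES) + ["N"])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-nucleotide call {calls[i, j]!r} for haplotype "
                f"{ids[i]} at site index {j}"
            )
        self.ids = list(ids)
        self.calls = calls
        self.sites = sites

    @property
    def n_haplotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Fraction of ``N`` calls per haplotype."""
        frac = (self.calls == "N").mean(axis=1)
        return pd.Series(frac, index=self.ids, name="missing_fraction")

    def subset(self, haplotypes: Sequence[str] | None = None,
               site_mask: np.ndarray | None = None) -> "HaplotypeMatrix":
        ids = self.ids if haplotypes is None else list(haplotypes)
        rows = [self.ids.index(h) for h in ids]
        calls = self.calls[rows]
        sites = self.sites
        if site_mask is not None:
            calls = calls[:, site_mask]
            sites = sites.loc[np.asarray(site_mask)].reset_index(drop=True)
        return HaplotypeMatrix(ids, calls, sites)

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])

    def indicator_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Encode calls as 0/1 minor-allele indicators with missing = -1.

        Returns ``(codes, biallelic)`` where ``codes`` has shape
        ``(n_haplotypes, n_sites)`` (int8; 1 = site's first-observed allele,
        0 = second, -1 = missing) and ``biallelic`` flags sites with exactly
        two observed alleles among called haplotypes.  Sites with one or more
        than two alleles get all-(-1) codes and ``biallelic=False``.
        """
        codes = np.full(self.calls.shape, -1, dtype=np.int8)
        biallelic = np.zeros(self.n_sites, dtype=bool)
        calls = self.calls
        called = calls != "N"
        for j in range(self.n_sites):
            col = calls[:, j]
            m = called[:, j]
            alleles = np.unique(col[m])
            if alleles.size != 2:
                continue
            biallelic[j] = True
            codes[m, j] = (col[m] == alleles[0]).astype(np.int8)
        return codes, biallelic

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<HaplotypeMatrix {self.n_haplotypes} haplotypes x "
                f"{self.n_sites} sites>")


def write_haplotypes(matrix: HaplotypeMatrix, path) -> None:
    """Write the TSV dialect: header of haplotype ids, one row per site."""
    ref = matrix.sites["ref"] if "ref" in matrix.sites else pd.Series(
        ["N"] * matrix.n_sites)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\t" + "\t".join(matrix.ids) + "\n")
        for j in range(matrix.n_sites):
            row = matrix.sites.iloc[j]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{ref.iloc[j]}\t"
                     + "\t".join(matrix.calls[:, j]) + "\n")


def read_haplotypes(path) -> HaplotypeMatrix:
    """Read the haplotype TSV dialect written by :func:`write_haplotypes`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "pos", "ref"]
    if list(df.columns[:3]) != fixed:
        raise ValidationError(f"haplotype file must start with columns {fixed}")
    ids = list(df.columns[3:])
    calls = df[ids].to_numpy(dtype="<U1").T
    sites = df[fixed].copy()
    return HaplotypeMatrix(ids, calls, sites)


# ---------------------------------------------------------------------------
# PoolCounts / sync format
# ---------------------------------------------------------------------------


def _normalize_design(design, n_samples: int) -> pd.DataFrame:
    """Accept a DataFrame / sequence of tuples; return the design table.

    Each entry is ``(replicate, generation[, timepoint])``; the timepoint
    label defaults to ``F{generation}``.  Timepoints let a sample taken at a
    deviating generation fill a design slot (the F23-for-R2 quirk).
    """
    if isinstance(design, pd.DataFrame):
        df = design.copy().reset_index(drop=True)
    else:
        rows = []
        for entry in design:
            entry = tuple(entry)
            if len(entry) == 2:
                rep, gen = entry
                tp = None
            else:
                rep, gen, tp = entry[:3]
            rows.append({"replicate": rep, "generation": gen, "timepoint": tp})
        df = pd.DataFrame(rows)
    if "timepoint" not in df.columns:
        df["timepoint"] = None
    df["timepoint"] = [
        tp if isinstance(tp, str) and tp else f"F{gen}"
        for tp, gen in zip(df["timepoint"], df["generation"])
    ]
    if len(df) != n_samples:
        raise DesignError(
            f"design describes {len(df)} samples but sync file has {n_samples}")
    if "sample" not in df.columns:
        df.insert(0, "sample", [f"{r}_{t}" for r, t in
                                zip(df["replicate"], df["timepoint"])])
    return df[["sample", "replicate", "generation", "timepoint"]]


class PoolCounts:
    """Pool-Seq allele counts per site and sample (sync layout).

    ``counts`` has shape ``(n_sites, n_samples, 6)`` in sync column order
    A:T:C:G:N:del.  Allele frequencies are computed over A/C/G/T only; the
    N and del columns are carried through I/O untouched.
    """

    def __init__(self, sites: pd.DataFrame, counts: np.ndarray, design):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 3 or counts.shape[2] != 6:
            raise ValidationError("counts must have shape (sites, samples, 6)")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.sites = _check_sites(sites)
        if counts.shape[0] != len(self.sites):
            raise ValidationError("counts rows do not match site table")
        self.counts = counts
        self.design = _normalize_design(design, counts.shape[1])

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def coverage(self, acgt_only: bool = True) -> np.ndarray:
        """Read depth per site x sample (by default over A/C/G/T)."""
        if acgt_only:
            return self.counts[:, :, _ACGT_IN_SYNC].sum(axis=2)
        return self.counts.sum(axis=2)

    def allele_counts(self, allele: str) -> np.ndarray:
        idx = SYNC_ALLELES.index(allele)
        return self.counts[:, :, idx]

    def frequencies(self, alleles: Sequence[str]) -> np.ndarray:
        """Frequency of the given per-site allele in every sample.

        ``alleles`` gives one nucleotide per site; returns an array of shape
        ``(n_sites, n_samples)`` with NaN where A/C/G/T coverage is zero.
        """
        alleles = np.asarray(alleles, dtype="<U1")
        if alleles.shape != (self.n_sites,):
            raise ValidationError("need one allele per site")
        cov = self.coverage().astype(float)
        sel = np.zeros((self.n_sites, self.n_samples), dtype=float)
        for letter in NUCLEOTIDES:
            mask = alleles == letter
            if mask.any():
                sel[mask] = self.allele_counts(letter)[mask]
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(cov > 0, sel / cov, np.nan)
        return freq

    def samples_for(self, timepoint: str | None = None,
                    replicate: str | None = None) -> np.ndarray:
        """Column indices matching a timepoint and/or replicate."""
        mask = np.ones(self.n_samples, dtype=bool)
        if timepoint is not None:
            mask &= (self.design["timepoint"] == timepoint).to_numpy()
        if replicate is not None:
            mask &= (self.design["replicate"] == replicate).to_numpy()
        return np.flatnonzero(mask)

    def site_lookup(self) -> dict[tuple, int]:
        return {(c, p): i for i, (c, p) in
                enumerate(zip(self.sites["chrom"], self.sites["pos"]))}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PoolCounts {self.n_sites} sites x {self.n_samples} samples>"


_COUNT_RE = re.compile(r"^\d+(:\d+){5}$")


def read_sync(path, design) -> PoolCounts:
    """Read a PoPoolation2 synchronized pileup.

    Lines are ``chrom pos ref A:T:C:G:N:del [x k samples]`` (tab-separated).
    ``design`` maps the k sample columns, in order, to
    ``(replicate, generation[, timepoint])``.
    """
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    rows: list[list[list[int]]] = []
    n_samples = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(f"line {lineno}: fewer than 4 fields")
            chrom, pos, ref = fields[0], fields[1], fields[2]
            sample_fields = fields[3:]
            if n_samples is None:
                n_samples = len(sample_fields)
            elif len(sample_fields) != n_samples:
                raise SyncParseError(
                    f"line {lineno}: expected {n_samples} sample columns, "
                    f"got {len(sample_fields)}")
            row = []
            for f in sample_fields:
                if not _COUNT_RE.match(f):
                    raise SyncParseError(
                        f"line {lineno}: malformed count field {f!r}")
                row.append([int(x) for x in f.split(":")])
            chroms.append(chrom)
            poss.append(int(pos))
            refs.append(ref)
            rows.append(row)
    if n_samples is None:
        raise SyncParseError(f"{path}: empty sync file")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs})
    counts = np.array(rows, dtype=np.int64)
    return PoolCounts(sites, counts, design)


def write_sync(pool: PoolCounts, path) -> None:
    with open(path, "w") as fh:
        for i in range(pool.n_sites):
            row = pool.sites.iloc[i]
            fields = [":".join(str(int(c)) for c in pool.counts[i, s])
                      for s in range(pool.n_samples)]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row.get('ref', 'N')}\t"
                     + "\t".join(fields) + "\n")


def read_design(path) -> pd.DataFrame:
    """Read a design TSV with columns replicate, generation[, timepoint]."""
    df = pd.read_csv(path, sep="\t")
    if not {"replicate", "generation"}.issubset(df.columns):
        raise DesignError("design file needs columns: replicate, generation")
    return df


# ---------------------------------------------------------------------------
# RecombMap
# ---------------------------------------------------------------------------


class RecombMap:
    """Piecewise-constant recombination map (cM/Mb per physical window).

    Windows must tile each chromosome without gaps or overlaps.  The genetic
    position of a 1-based coordinate ``pos`` is the integral of the rate from
    the chromosome start to ``pos``; queries are allowed up to ``end + 1`` of
    the last window (the right edge of the tiled interval).
    """

    def __init__(self, windows: pd.DataFrame):
        req = {"chrom", "start", "end", "rate"}
        if not req.issubset(windows.columns):
            raise ValidationError(f"recombination map needs columns {sorted(req)}")
        if (windows["rate"] < 0).any():
            raise ValidationError("recombination rates must be >= 0")
        self.windows = windows.reset_index(drop=True)
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray,
                                         np.ndarray]] = {}
        for chrom, grp in self.windows.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            rates = grp["rate"].to_numpy(dtype=float)
            if (ends < starts).any():
                raise ValidationError(f"window with end < start on {chrom}")
            if np.any(starts[1:] != ends[:-1] + 1):
                raise ValidationError(
                    f"windows on {chrom} must tile without gaps or overlaps")
            # cumulative cM at each window start (continuous coordinates)
            lengths_mb = (ends - starts + 1) / 1e6
            cum = np.concatenate([[0.0], np.cumsum(lengths_mb * rates)])
            self._per_chrom[chrom] = (starts, ends, rates, cum)

    @classmethod
    def uniform(cls, chrom_lengths: Mapping[str, int], rate: float,
                window: int = 100_000) -> "RecombMap":
        """Constant-rate map tiled in ``window``-bp pieces (testing helper)."""
        rows = []
        for chrom, length in chrom_lengths.items():
            start = 1
            while start <= length:
                end = min(start + window - 1, length)
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "rate": rate})
                start = end + 1
        return cls(pd.DataFrame(rows))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._per_chrom)

    def _locate(self, chrom: str):
        try:
            return self._per_chrom[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} not in map") from None

    def chrom_span(self, chrom: str) -> tuple[int, int]:
        starts, ends, _, _ = self._locate(chrom)
        return int(starts[0]), int(ends[-1])

    def genetic_position(self, chrom: str, pos) -> np.ndarray | float:
        """cM from the chromosome start to ``pos`` (scalar or array)."""
        starts, ends, rates, cum = self._locate(chrom)
        p = np.asarray(pos, dtype=np.int64)
        if np.any(p < starts[0]) or np.any(p > ends[-1] + 1):
            raise ValidationError(
                f"position outside map for {chrom}: valid range "
                f"[{starts[0]}, {ends[-1] + 1}]")
        idx = np.clip(np.searchsorted(starts, p, side="right") - 1, 0,
                      len(starts) - 1)
        gp = cum[idx] + (p - starts[idx]) * rates[idx] / 1e6
        return float(gp) if np.isscalar(pos) else gp

    def genetic_distance(self, chrom: str, pos1: int, pos2: int) -> float:
        """Integral of the local rate over ``[pos1, pos2]`` in cM."""
        if pos1 > pos2:
            raise ValidationError("pos1 must be <= pos2")
        return float(self.genetic_position(chrom, pos2)
                     - self.genetic_position(chrom, pos1))

    def physical_position(self, chrom: str, cm: float) -> int:
        """Inverse of :meth:`genetic_position` (1-based bp; ties break left)."""
        starts, ends, rates, cum = self._locate(chrom)
        if cm < 0 or cm > cum[-1] + 1e-12:
            raise ValidationError(f"genetic position {cm} outside map")
        idx = int(np.clip(np.searchsorted(cum, cm, side="right") - 1, 0,
                          len(starts) - 1))
        if rates[idx] == 0:
            return int(starts[idx])
        off = (cm - cum[idx]) / rates[idx] * 1e6
        return int(starts[idx] + min(off, ends[idx] - starts[idx] + 1))

    def total_cm(self, chrom: str) -> float:
        return float(self._per_chrom[chrom][3][-1])

    def mean_rate(self, chrom: str, start: int, end: int) -> float:
        """Unweighted mean rate of all windows overlapping ``[start, end]``.

        This is the convention used to report a block's "local recombination
        rate": average over the 100-kb windows the block touches.
        """
        starts, ends, rates, _ = self._locate(chrom)
        overlap = (ends >= start) & (starts <= end)
        if not overlap.any():
            raise ValidationError("span overlaps no map window")
        return float(rates[overlap].mean())


def read_recomb_map(path) -> RecombMap:
    """Read a map TSV with columns chrom, start, end, rate (cM/Mb)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return RecombMap(df)


# ---------------------------------------------------------------------------
# Interval formats
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"BED record with <3 fields: {line!r}")
            row = {"chrom": f[0], "start": int(f[1]) + 1, "end": int(f[2])}
            if len(f) > 3:
                row["name"] = f[3]
            rows.append(row)
    return pd.DataFrame(rows)


_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_gff(path, feature_types: Iterable[str] | None = None) -> pd.DataFrame:
    """Read GFF3 records (1-based inclusive already) into an interval table.

    ``name`` is taken from the ``Name=`` attribute, falling back to ``ID=``.
    """
    wanted = set(feature_types) if feature_types is not None else None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValidationError(f"GFF record with <9 fields: {line!r}")
            ftype = f[2]
            if wanted is not None and ftype not in wanted:
                continue
            attrs = dict(_GFF_ATTR_RE.findall(f[8]))
            rows.append({
                "chrom": f[0], "start": int(f[3]), "end": int(f[4]),
                "feature": ftype,
                "name": attrs.get("Name", attrs.get("ID", "")),
            })
    return pd.DataFrame(rows)


def read_intervals(path) -> pd.DataFrame:
    """Dispatch on extension: ``.bed`` vs ``.gff``/``.gff3``."""
    p = str(path)
    if p.endswith(".bed"):
        return read_bed(path)
    if p.endswith((".gff", ".gff3")):
        return read_gff(path)
    raise ValidationError(f"cannot infer interval format of {p!r}")
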