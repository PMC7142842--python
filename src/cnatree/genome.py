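"""Genomic bin scaffold.

Everything downstream — counting, normalization, segmentation, event
calling — is indexed against a single ordered set of fixed-width genomic
bins (default 500 kb).  :class:`GenomeBins` carries, per bin, the
coordinates, the GC fraction used for bias correction, and a usability
flag; chromosomes flagged as sex chromosomes are excluded from event
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenomeBins"]


@dataclass
class GenomeBins:
    """Ordered fixed-width genomic bins with GC content and usability mask.

    Parameters
    ----------
    table
        DataFrame with columns ``chrom`` (str), ``start`` (int, 0-based),
        ``end`` (int, half-open), ``gc`` (float in [0, 1]) and ``usable``
        (bool).  Bins must be sorted, contiguous and non-overlapping
        within each chromosome.
    sex_chroms
        Chromosome names to treat as sex chromosomes.
    bin_size
        Nominal bin width in bp; every bin except possibly the last of a
        chromosome must have exactly this width.
    """

    table: pd.DataFrame
    sex_chroms: frozenset = field(default_factory=frozenset)
    bin_size: int = 500_000

    def __post_init__(self) -> None:
        self.sex_chroms = frozenset(self.sex_chroms)
        req = {"chrom", "start", "end", "gc", "usable"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"bin table missing columns: {sorted(missing)}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        t = self.table.reset_index(drop=True)
        gc = t["gc"].to_numpy(float)
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("gc values must lie in [0, 1]")
        for chrom, sub in t.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted bin")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"{chrom}: bins not contiguous/sorted")
            widths = ends - starts
            if np.any(widths[:-1] != self.bin_size) or widths[-1] > self.bin_size:
                raise ValueError(
                    f"{chrom}: bin widths must equal bin_size "
                    f"(last bin may be shorter)"
                )
        self.table = t

    # -- basic accessors ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def usable(self) -> np.ndarray:
        return self.table["usable"].to_numpy(bool)

    @property
    def gc(self) -> np.ndarray:
        return self.table["gc"].to_numpy(float)

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of bins on non-sex chromosomes."""
        return ~self.table["chrom"].isin(self.sex_chroms).to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        """Global bin-index slice for each chromosome, in genome order."""
        out: dict[str, slice] = {}
        chroms = self.table["chrom"].to_numpy()
        start = 0
        for chrom in self.chroms:
            n = int((chroms == chrom).sum())
            out[chrom] = slice(start, start + n)
            start += n
        return out

    def with_usable(self, usable: np.ndarray) -> "GenomeBins":
        """Return a copy with a replaced usability mask."""
        usable = np.asarray(usable, bool)
        if usable.shape != (self.n_bins,):
            raise ValueError("usable mask has wrong length")
        t = self.table.copy()
        t["usable"] = usable
        return replace(self, table=t)

    def is_sex(self, chrom: str) -> bool:
        return chrom in self.sex_chroms

    # -- BED round-trip ----------------------------------------------------

    def to_bed(self, path) -> None:
        """Write bins as BED with gc, usable and sex-flag columns."""
        t = self.table.copy()
        t["name"] = [f"bin{i}" for i in range(len(t))]
        t["gc"] = t["gc"].map(lambda v: f"{v:.6f}")
        t["usable"] = t["usable"].astype(int)
        t["is_sex"] = t["chrom"].isin(self.sex_chroms).astype(int)
        t[["chrom", "start", "end", "name", "gc", "usable", "is_sex"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path, bin_size: int = 500_000) -> "GenomeBins":
        t = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "gc", "usable", "is_sex"],
            dtype={"chrom": str},
        )
        sex = frozenset(t.loc[t["is_sex"] == 1, "chrom"])
        t = t[["chrom", "start", "end", "gc", "usable"]].copy()
        t["usable"] = t["usable"].astype(bool)
        return cls(t, sex_chroms=sex, bin_size=bin_size)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GenomeBins):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and self.sex_chroms == other.sex_chroms
            and self.table.shape == other.table.shape
            and (self.table["chrom"] == other.table["chrom"]).all()
            and (self.table["start"] == other.table["start"]).all()
            and (self.table["end"] == other.table["end"]).all()
            and np.allclose(self.gc, other.gc, atol=1e-9)
            and (self.usable == other.usable).all()
        )
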