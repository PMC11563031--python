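"""Per-population allele-frequency panels.

A :class:`FrequencyPanel` holds, for a set of biallelic SNPs and a set of
populations, the observed allele frequency ``p`` and the number of observed
allele copies (2 x diploid individuals with data) per SNP and population,
plus a per-SNP jackknife block label.  Frequencies are stored as NaN where a
population has no data (count 0) at a SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrequencyPanel", "assign_blocks"]


class PanelError(ValueError):
    """Raised for structurally invalid panels or unknown population labels."""


def assign_blocks(
    chrom: np.ndarray | None,
    pos: np.ndarray | None,
    *,
    block_size_mb: float = 5.0,
    snps_per_block: int = 500,
) -> np.ndarray:
    """Assign contiguous jackknife block labels.

    SNPs are grouped into contiguous blocks of ``block_size_mb`` megabases per
    chromosome; if positions are absent, fixed chunks of ``snps_per_block``
    consecutive SNPs are used instead.  Labels are consecutive integers
    starting at 0, in genome order.
    """
    if chrom is None or pos is None:
        n = len(chrom) if chrom is not None else len(pos)  # type: ignore[arg-type]
        return np.arange(n) // snps_per_block
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=float)
    span = np.floor(pos / (block_size_mb * 1e6)).astype(int)
    # factorize (chrom, span) pairs preserving genome order
    labels = np.zeros(len(pos), dtype=int)
    current = 0
    for i in range(1, len(pos)):
        if chrom[i] != chrom[i - 1] or span[i] != span[i - 1]:
            current += 1
        labels[i] = current
    return labels


@dataclass
class FrequencyPanel:
    """Allele frequencies and counts for SNPs x populations.

    Attributes
    ----------
    snp_ids : array of str
    chrom, pos : per-SNP chromosome and 1-based position (may be None)
    freqs : (S, P) float array, NaN = missing
    counts : (S, P) int array of observed allele copies; 0 = missing
    blocks : (S,) int array of contiguous jackknife block labels
    pop_names : ordered unique population labels
    meta : free-form provenance dictionary (e.g. simulator settings)
    """

    snp_ids: np.ndarray
    chrom: np.ndarray | None
    pos: np.ndarray | None
    freqs: np.ndarray
    counts: np.ndarray
    blocks: np.ndarray
    pop_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.counts = np.asarray(self.counts)
        self.blocks = np.asarray(self.blocks)
        self.pop_names = list(self.pop_names)
        S = len(self.snp_ids)
        P = len(self.pop_names)
        if self.freqs.shape != (S, P) or self.counts.shape != (S, P):
            raise PanelError(
                f"shape mismatch: {S} SNPs x {P} populations, "
                f"freqs {self.freqs.shape}, counts {self.counts.shape}"
            )
        if len(self.blocks) != S:
            raise PanelError("blocks must have one label per SNP")
        if len(set(self.pop_names)) != P:
            raise PanelError("population names must be unique")
        missing = self.counts == 0
        self.freqs = np.where(missing, np.nan, self.freqs)
        observed = self.freqs[~missing]
        if observed.size and (np.nanmin(observed) < -1e-12 or np.nanmax(observed) > 1 + 1e-12):
            raise PanelError("frequencies must lie in [0, 1] where data exist")
        # normalize block labels to 0..B-1 preserving order, check contiguity
        _, first_idx, inv = np.unique(self.blocks, return_index=True, return_inverse=True)
        order = np.argsort(first_idx)
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        labels = rank[inv]
        if np.any(np.diff(labels) < 0):
            raise PanelError("block labels must form contiguous runs in genome order")
        self.blocks = labels

    # -- basic accessors -------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def n_blocks(self) -> int:
        return int(self.blocks.max()) + 1 if len(self.blocks) else 0

    def pop_index(self, name: str) -> int:
        try:
            return self.pop_names.index(name)
        except ValueError:
            raise PanelError(
                f"unknown population {name!r}; panel has {', '.join(self.pop_names)}"
            ) from None

    def complete_mask(self, pops: list[str]) -> np.ndarray:
        """SNPs with data in every listed population (complete-cases policy)."""
        idx = [self.pop_index(p) for p in pops]
        return (self.counts[:, idx] > 0).all(axis=1)

    # -- tabular round trip ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {
            "snp_id": self.snp_ids,
            "chrom": self.chrom if self.chrom is not None else "1",
            "pos": self.pos if self.pos is not None else np.arange(1, self.n_snps + 1),
            "block": self.blocks,
        }
        for j, p in enumerate(self.pop_names):
            data[f"{p}.freq"] = self.freqs[:, j]
            data[f"{p}.count"] = self.counts[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, block_size_mb: float = 5.0) -> "FrequencyPanel":
        pops = [c[:-5] for c in df.columns if c.endswith(".freq")]
        if not pops:
            raise PanelError("no '<pop>.freq' columns found")
        freqs = df[[f"{p}.freq" for p in pops]].to_numpy(dtype=float)
        counts = df[[f"{p}.count" for p in pops]].to_numpy(dtype=np.int64)
        chrom = df["chrom"].to_numpy() if "chrom" in df else None
        pos = df["pos"].to_numpy() if "pos" in df else None
        if "block" in df:
            blocks = df["block"].to_numpy(dtype=int)
        else:
            blocks = assign_blocks(chrom, pos, block_size_mb=block_size_mb)
        return cls(
            snp_ids=df["snp_id"].to_numpy(),
            chrom=chrom,
            pos=pos,
            freqs=freqs,
            counts=counts,
            blocks=blocks,
            pop_names=pops,
        )
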