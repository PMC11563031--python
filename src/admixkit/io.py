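"""Readers and writers: EIGENSTRAT genotypes, frequency tables, results.

EIGENSTRAT is the genotype triple used across the ADMIXTOOLS ecosystem:
``.geno`` (one character per individual per SNP: 0/1/2 allele copies, 9 =
missing), ``.snp`` (ID, chromosome, genetic position, physical position,
alleles) and ``.ind`` (individual, sex, population label).  Individuals are
pooled into populations by their ``.ind`` label, in first-appearance order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FrequencyPanel, assign_blocks

__all__ = [
    "read_eigenstrat",
    "write_eigenstrat",
    "read_freq_table",
    "write_freq_table",
    "write_results",
]


class FormatError(ValueError):
    pass


def read_eigenstrat(
    geno_path, snp_path, ind_path, *, block_size_mb: float = 5.0
) -> FrequencyPanel:
    """Read an EIGENSTRAT trio into a per-population frequency panel."""
    geno_path, snp_path, ind_path = Path(geno_path), Path(snp_path), Path(ind_path)

    inds = []
    for lineno, line in enumerate(ind_path.read_text().splitlines(), 1):
        tok = line.split()
        if not tok:
            continue
        if len(tok) != 3:
            raise FormatError(f"{ind_path.name} line {lineno}: expected 3 fields, got {len(tok)}")
        inds.append(tok)
    pop_of = [t[2] for t in inds]
    pop_names = list(dict.fromkeys(pop_of))
    pop_idx = np.array([pop_names.index(p) for p in pop_of])
    n_ind = len(inds)

    snp_rows = []
    seen = set()
    for lineno, line in enumerate(snp_path.read_text().splitlines(), 1):
        tok = line.split()
        if not tok:
            continue
        if len(tok) not in (4, 6):
            raise FormatError(f"{snp_path.name} line {lineno}: expected 4 or 6 fields")
        if tok[0] in seen:
            raise FormatError(f"{snp_path.name} line {lineno}: duplicate SNP ID {tok[0]!r}")
        seen.add(tok[0])
        snp_rows.append((tok[0], tok[1], int(tok[3])))
    n_snps = len(snp_rows)

    geno_lines = [l for l in geno_path.read_text().splitlines() if l]
    if len(geno_lines) != n_snps:
        raise FormatError(
            f"{geno_path.name}: {len(geno_lines)} genotype lines but {n_snps} SNPs in {snp_path.name}"
        )
    G = np.empty((n_snps, n_ind), dtype=np.int8)
    lut = np.full(128, -1, dtype=np.int8)
    for ch, v in zip("0129", (0, 1, 2, 9)):
        lut[ord(ch)] = v
    for i, line in enumerate(geno_lines):
        if len(line) != n_ind:
            raise FormatError(
                f"{geno_path.name} line {i + 1}: {len(line)} genotypes for {n_ind} individuals"
            )
        row = lut[np.frombuffer(line.encode(), dtype=np.uint8)]
        if (row < 0).any():
            bad = line[int(np.argmax(row < 0))]
            raise FormatError(f"{geno_path.name} line {i + 1}: unknown genotype character {bad!r}")
        G[i] = row

    P = len(pop_names)
    freqs = np.full((n_snps, P), np.nan)
    counts = np.zeros((n_snps, P), dtype=np.int64)
    present = G != 9
    for j in range(P):
        cols = pop_idx == j
        n_obs = present[:, cols].sum(axis=1)
        counts[:, j] = 2 * n_obs
        alt = np.where(present[:, cols], G[:, cols], 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, j] = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    chrom = np.array([r[1] for r in snp_rows])
    pos = np.array([r[2] for r in snp_rows])
    return FrequencyPanel(
        snp_ids=np.array([r[0] for r in snp_rows]),
        chrom=chrom,
        pos=pos,
        freqs=freqs,
        counts=counts,
        blocks=assign_blocks(chrom, pos, block_size_mb=block_size_mb),
        pop_names=pop_names,
    )


def write_eigenstrat(prefix, genotypes: np.ndarray, panel: FrequencyPanel, samples_per_pop: int) -> None:
    """Write a genotype matrix plus panel metadata as an EIGENSTRAT trio."""
    prefix = Path(prefix)
    with open(f"{prefix}.geno", "w") as fh:
        for row in genotypes:
            fh.write("".join("9" if v == 9 else str(int(v)) for v in row) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for i in range(panel.n_snps):
            chrom = panel.chrom[i] if panel.chrom is not None else "1"
            pos = panel.pos[i] if panel.pos is not None else i + 1
            fh.write(f"{panel.snp_ids[i]}\t{chrom}\t0.0\t{pos}\tA\tG\n")
    with open(f"{prefix}.ind", "w") as fh:
        for pop in panel.pop_names:
            for k in range(samples_per_pop):
                fh.write(f"{pop}_{k}\tU\t{pop}\n")


def read_freq_table(path, *, block_size_mb: float = 5.0) -> FrequencyPanel:
    """Read a tab-separated panel: snp_id, chrom, pos[, block], <pop>.freq, <pop>.count."""
    df = pd.read_csv(path, sep="\t")
    return FrequencyPanel.from_frame(df, block_size_mb=block_size_mb)


def write_freq_table(panel: FrequencyPanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results(result, prefix, *, config: dict | None = None, seed: int | None = None) -> list[str]:
    """Write a fit (or a list of FStatResults) as deterministic text outputs.

    A FitResult produces <prefix>.graph.txt, <prefix>.dot,
    <prefix>.residuals.tsv and <prefix>.json (score, parameters, rank report,
    config echo).  A list of f-statistics produces <prefix>.fstats.tsv.
    """
    from . import __version__
    from .fitting import FitResult
    from .fstats import FStatResult
    from .graph import serialize_graph

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    if isinstance(result, FitResult):
        p = f"{prefix}.graph.txt"
        Path(p).write_text(serialize_graph(result.graph))
        written.append(p)
        p = f"{prefix}.dot"
        Path(p).write_text(serialize_graph(result.graph, format="dot"))
        written.append(p)
        if result.residuals is not None:
            p = f"{prefix}.residuals.tsv"
            result.residuals.to_csv(p, sep="\t", index=False, float_format="%.10g")
            written.append(p)
        ident = result.identifiability
        payload = {
            "score": result.score,
            "lsq": result.lsq,
            "converged": result.converged,
            "n_restarts_used": result.n_restarts_used,
            "lengths": {k: round(v, 12) for k, v in result.lengths.items()},
            "alphas": {k: round(v, 12) for k, v in result.alphas.items()},
            "base_pop": result.basis.base_pop,
            "populations": result.basis.pops,
            "n_snps": result.basis.n_snps,
            "n_blocks": result.basis.n_blocks,
            "diag_reg": result.basis.diag_reg,
            "identifiability": None
            if ident is None
            else {
                "rank": ident.rank,
                "n_parameters": ident.n_parameters,
                "n_constraints": ident.n_constraints,
                "n_free_formula": ident.n_free_formula,
                "underdetermined": ident.underdetermined,
                "null_space": ident.null_space,
            },
            "seed": seed,
            "config": config or {},
            "version": __version__,
        }
        p = f"{prefix}.json"
        Path(p).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)
        return written

    if isinstance(result, (list, tuple)) and all(isinstance(r, FStatResult) for r in result):
        rows = [
            {
                "kind": r.kind,
                "pops": ",".join(r.pops),
                "value": r.value,
                "se": r.se,
                "z": r.z,
                "n_snps": r.n_snps,
                "n_blocks": r.n_blocks,
            }
            for r in result
        ]
        p = f"{prefix}.fstats.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
        return written

    raise FormatError(f"do not know how to write {type(result).__name__}")
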