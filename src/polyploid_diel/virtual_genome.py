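"""Discriminating-SNP calling and virtual progenitor genome construction.

To quantify homoeolog-specific expression in an allopolyploid whose second
progenitor lacks a usable reference, a *virtual* progenitor genome is built by
substituting, into the first progenitor's reference, the alleles at sites that
discriminate the two subgenomes: sites where every progenitor-2 read carries
one non-reference allele (homogenic) while hybrid reads carry both alleles
(heterogenic, one from each subgenome).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "call_discriminating_snps",
    "build_virtual_genome",
    "read_fasta",
    "write_fasta",
    "read_pileup_tsv",
]

_ALLELES = ("A", "C", "G", "T")


def call_discriminating_snps(
    sites: pd.DataFrame,
    min_depth_p2: int = 5,
    min_depth_hyb: int = 5,
    hyb_minor_fraction: float = 0.2,
    noise_fraction: float = 0.05,
) -> pd.DataFrame:
    """Call SNPs that separate the two homoeologous genomes.

    A site is emitted iff

    a. progenitor-2 depth >= ``min_depth_p2`` and *all* progenitor-2 reads
       (after discarding alleles jointly below ``noise_fraction`` of depth)
       carry one single non-reference allele, and
    b. hybrid depth >= ``min_depth_hyb`` and both the reference allele and
       that alt allele reach fraction >= ``hyb_minor_fraction`` in hybrid
       reads.

    ``sites`` needs columns ``chrom, pos, ref, p2_A..p2_T, hyb_A..hyb_T``.
    Sites whose minor alleles exceed the noise budget are skipped with a
    logged warning.  Returns a SNP table ``chrom, pos, ref, alt``.
    """
    if min_depth_p2 <= 0 or min_depth_hyb <= 0:
        raise ValueError("depth thresholds must be positive")
    if not 0.0 < hyb_minor_fraction <= 0.5:
        raise ValueError("hyb_minor_fraction must be in (0, 0.5]")

    p2 = sites[[f"p2_{b}" for b in _ALLELES]].to_numpy(dtype=float)
    hyb = sites[[f"hyb_{b}" for b in _ALLELES]].to_numpy(dtype=float)
    ref_idx = pd.Categorical(sites["ref"], categories=_ALLELES).codes
    n = len(sites)
    rows = np.arange(n)

    def _denoise(depths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Keep the two most frequent alleles; return (cleaned, skip_mask)."""
        order = np.argsort(depths, axis=1)  # ascending
        cleaned = depths.copy()
        minor = np.zeros(n)
        for k in (0, 1):  # zero out the two least frequent alleles
            idx = order[:, k]
            minor += cleaned[rows, idx]
            cleaned[rows, idx] = 0.0
        total = depths.sum(axis=1)
        skip = (minor > 0) & (minor / np.maximum(total, 1) >= noise_fraction)
        return cleaned, skip

    p2_clean, p2_skip = _denoise(p2)
    hyb_clean, hyb_skip = _denoise(hyb)
    skip = p2_skip | hyb_skip
    n_skipped = int(skip.sum())
    if n_skipped:
        logger.warning("skipped %d sites with excess multi-allelic noise", n_skipped)

    p2_depth = p2_clean.sum(axis=1)
    p2_ref = p2_clean[rows, ref_idx]
    # the single non-reference allele carried by all progenitor-2 reads
    p2_nonref = p2_clean.copy()
    p2_nonref[rows, ref_idx] = -1.0
    alt_idx = np.argmax(p2_nonref, axis=1)
    p2_alt = p2_clean[rows, alt_idx]
    homogenic = (p2_depth >= min_depth_p2) & (p2_ref == 0) & (p2_alt == p2_depth)

    hyb_depth = hyb_clean.sum(axis=1)
    hyb_ref = hyb_clean[rows, ref_idx]
    hyb_alt = hyb_clean[rows, alt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        fr_ref = np.where(hyb_depth > 0, hyb_ref / np.maximum(hyb_depth, 1), 0.0)
        fr_alt = np.where(hyb_depth > 0, hyb_alt / np.maximum(hyb_depth, 1), 0.0)
    heterogenic = (
        (hyb_depth >= min_depth_hyb)
        & (fr_ref >= hyb_minor_fraction)
        & (fr_alt >= hyb_minor_fraction)
    )

    keep = homogenic & heterogenic & ~skip
    out = pd.DataFrame(
        {
            "chrom": sites.loc[keep, "chrom"].to_numpy(),
            "pos": sites.loc[keep, "pos"].to_numpy(),
            "ref": sites.loc[keep, "ref"].to_numpy(),
            "alt": np.array(_ALLELES)[alt_idx[keep]],
        }
    )
    return out.reset_index(drop=True)


def build_virtual_genome(
    reference: dict[str, str], snps: pd.DataFrame
) -> dict[str, str]:
    """Substitute alt alleles into the reference at every SNP position.

    Positions are 1-based.  Raises if a SNP's stated ref allele disagrees
    with the reference base at that position, naming ``chrom:pos``.
    """
    out: dict[str, np.ndarray] = {
        chrom: np.frombuffer(seq.encode(), dtype="S1").copy()
        for chrom, seq in reference.items()
    }
    for chrom, sub in snps.groupby("chrom", sort=False):
        if chrom not in out:
            raise KeyError(f"SNP table names unknown sequence {chrom!r}")
        arr = out[chrom]
        pos = sub["pos"].to_numpy()
        if (pos < 1).any() or (pos > len(arr)).any():
            bad = pos[(pos < 1) | (pos > len(arr))][0]
            raise ValueError(f"SNP position out of range: {chrom}:{bad}")
        have = arr[pos - 1].astype("U1")
        want = sub["ref"].to_numpy(dtype="U1")
        mism = have != want
        if mism.any():
            p = pos[mism][0]
            raise ValueError(
                f"reference allele mismatch at {chrom}:{p}: "
                f"expected {want[mism][0]}, found {have[mism][0]}"
            )
        arr[pos - 1] = sub["alt"].to_numpy(dtype="S1")
    return {chrom: arr.tobytes().decode() for chrom, arr in out.items()}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref"} | {
        f"{pool}_{b}" for pool in ("p2", "hyb") for b in _ALLELES
    }
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    return sites
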