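"""Synthetic-data generator for the allopolyploid diel-transcriptome pipeline.

Everything the downstream stages consume can be generated here without any
sequencing data: a pair of diverged parental genomes joined in a hybrid,
discriminating-SNP pileup evidence, aligned read pairs (fragments) with known
subgenome of origin, and negative-binomial diurnal count matrices with planted
homoeolog-expression-bias (HEB) categories and 24-h rhythmic components.

The default design mirrors a long-day diurnal RNA-seq experiment: six sampling
times spaced 4 h over one 24-h cycle, three biological replicates, a 20 h
light / 4 h dark photoperiod (lights on 4:00), and five expression channels —
two diploid progenitors (``P1``, ``P2``), the two allopolyploid subgenomes
(``BdSub``, ``BsSub``) and an autotetraploid of the first progenitor
(``Auto``).  Planted truth is carried alongside every artefact so parameter
recovery can be measured exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "HEB_CATEGORIES",
    "SimDesign",
    "SimBundle",
    "generate_parental_genomes",
    "simulate_pileups",
    "simulate_fragments",
    "make_gene_truth",
    "simulate_diel_counts",
    "draw_library_sizes",
    "generate_bundle",
    "write_bundle",
]

#: Expression channels: diploid progenitors, allopolyploid subgenomes, and the
#: induced autotetraploid of progenitor 1.
CHANNELS = ("P1", "P2", "BdSub", "BsSub", "Auto")

#: The five per-time-point HEB categories.
HEB_CATEGORIES = (
    "balance_retention",
    "bias_retention",
    "bias_gain",
    "bias_loss",
    "bias_switch",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimDesign:
    """Study design of one synthetic diurnal experiment.

    Parameters
    ----------
    n_genes : int
        Number of homoeologous gene groups to simulate.
    time_points_h : tuple of float
        Sampling clock hours, strictly increasing within one 24-h cycle.
    n_replicates : int
        Biological replicates per time point (>= 2).
    light_on_h, light_off_h : float
        Photoperiod boundaries on the clock axis (defaults: light 4:00-24:00).
    seed : int
        Master seed; every stochastic step derives its stream from it.
    """

    n_genes: int = 2000
    time_points_h: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)
    n_replicates: int = 3
    light_on_h: float = 4.0
    light_off_h: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        tp = np.asarray(self.time_points_h, dtype=float)
        if tp.ndim != 1 or len(tp) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(tp) <= 0) or tp[0] < 0 or tp[-1] >= 24.0:
            raise ValueError("time points must be strictly increasing within [0, 24)")

    @property
    def n_time_points(self) -> int:
        return len(self.time_points_h)


@dataclass
class SimBundle:
    """All artefacts of one synthetic experiment, with ground truth attached."""

    design: SimDesign
    reference: str
    diverged: str
    snps: pd.DataFrame
    pileups: pd.DataFrame
    fragments: pd.DataFrame
    truth: pd.DataFrame
    counts: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    library_sizes: pd.Series


# ---------------------------------------------------------------------------
# genomes and SNPs
# ---------------------------------------------------------------------------

def generate_parental_genomes(
    length: int,
    snp_rate: float,
    seed: int,
    chrom: str = "chr1",
) -> tuple[str, str, pd.DataFrame]:
    """Simulate a reference genome and a diverged parental copy.

    Each base of the reference mutates independently with probability
    ``snp_rate``; substituted bases are always different from the reference.
    Returns ``(reference, diverged, snp_table)`` where the SNP table has
    1-based positions and columns ``chrom, pos, ref, alt``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= snp_rate < 1.0:
        raise ValueError("snp_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ref_idx = rng.integers(0, 4, size=length)
    is_snp = rng.random(length) < snp_rate
    # shift by 1..3 in base space so alt != ref at every SNP
    shift = rng.integers(1, 4, size=length)
    alt_idx = np.where(is_snp, (ref_idx + shift) % 4, ref_idx)
    reference = "".join(_BASES[ref_idx])
    diverged = "".join(_BASES[alt_idx])
    pos = np.flatnonzero(is_snp)
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos + 1,
            "ref": _BASES[ref_idx[pos]],
            "alt": _BASES[alt_idx[pos]],
        }
    )
    return reference, diverged, snps


def _draw_allele_counts(
    rng: np.random.Generator,
    true_idx: np.ndarray,
    depth: int,
    error_rate: float,
) -> np.ndarray:
    """Multinomial allele-depth draws with uniform substitution error.

    ``true_idx`` gives, per site and per read slot, the index (0..3) of the
    error-free base.  Each read keeps it with probability ``1 - error_rate``
    and otherwise becomes one of the three other bases uniformly.
    """
    n_sites, depth_ = true_idx.shape
    err = rng.random(true_idx.shape) < error_rate
    jump = rng.integers(1, 4, size=true_idx.shape)
    obs = np.where(err, (true_idx + jump) % 4, true_idx)
    counts = np.zeros((n_sites, 4), dtype=int)
    for b in range(4):
        counts[:, b] = (obs == b).sum(axis=1)
    return counts


def simulate_pileups(
    reference: str,
    snps: pd.DataFrame,
    depth: int,
    error_rate: float,
    seed: int,
    decoy_factor: int = 10,
) -> pd.DataFrame:
    """Simulate allele-depth pileups for progenitor-2 and hybrid reads.

    True SNP sites: progenitor-2 reads carry the alt allele (homozygous),
    hybrid reads draw ref/alt 50:50 (heterozygous).  Decoy (non-SNP) sites
    are sampled at ``decoy_factor`` times the SNP count and both read pools
    carry the reference allele.  Sequencing error substitutes a read's base
    uniformly at rate ``error_rate``.

    Returns one row per site with columns ``chrom, pos, ref, p2_A..p2_T,
    hyb_A..hyb_T, is_true_snp``; the last column is ground truth for
    benchmarking and is never consumed by the SNP caller.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    base_to_idx = {b: i for i, b in enumerate("ACGT")}

    snp_pos = snps["pos"].to_numpy() if len(snps) else np.array([], dtype=int)
    ref_arr = np.frombuffer(reference.encode(), dtype="S1").astype("U1")
    non_snp = np.setdiff1d(np.arange(1, len(reference) + 1), snp_pos)
    n_decoys = min(decoy_factor * max(len(snp_pos), 1), len(non_snp))
    decoy_pos = np.sort(rng.choice(non_snp, size=n_decoys, replace=False))

    rows = []
    # order: true SNPs then decoys; shuffle not needed (caller sorts by pos)
    pos_all = np.concatenate([snp_pos, decoy_pos])
    is_true = np.concatenate(
        [np.ones(len(snp_pos), bool), np.zeros(len(decoy_pos), bool)]
    )
    ref_bases = ref_arr[pos_all - 1]
    ref_idx = np.array([base_to_idx[b] for b in ref_bases])
    alt_idx = np.concatenate(
        [
            np.array([base_to_idx[b] for b in snps["alt"]], dtype=int)
            if len(snps)
            else np.array([], dtype=int),
            ref_idx[len(snp_pos):],  # decoys: "alt" slot unused, ref everywhere
        ]
    )

    # progenitor-2: alt allele at SNPs, ref at decoys
    p2_truth = np.where(is_true[:, None], alt_idx[:, None], ref_idx[:, None])
    p2_truth = np.broadcast_to(p2_truth, (len(pos_all), depth))
    p2 = _draw_allele_counts(rng, p2_truth, depth, error_rate)

    # hybrid: 50/50 ref/alt at SNPs, ref at decoys
    pick_alt = rng.random((len(pos_all), depth)) < 0.5
    hyb_truth = np.where(
        is_true[:, None] & pick_alt, alt_idx[:, None], ref_idx[:, None]
    )
    hyb = _draw_allele_counts(rng, hyb_truth, depth, error_rate)

    out = pd.DataFrame({"chrom": "chr1", "pos": pos_all, "ref": ref_bases})
    for i, b in enumerate("ACGT"):
        out[f"p2_{b}"] = p2[:, i]
    for i, b in enumerate("ACGT"):
        out[f"hyb_{b}"] = hyb[:, i]
    out["is_true_snp"] = is_true
    out = out.sort_values("pos", kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def simulate_fragments(
    n: int,
    frag_snp_lambda: float,
    error_rate: float,
    seed: int,
    frag_len: int = 200,
    gene_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate hybrid read pairs with mismatch counts against both genomes.

    A fragment overlaps ``k ~ Poisson(frag_snp_lambda)`` discriminating SNPs
    and originates from one subgenome (50:50).  Sequencing errors at non-SNP
    positions mismatch both references identically, so only the SNP-overlap
    and the rare errors at SNP positions separate the two mismatch counts:

    * vs own genome: errors anywhere in the fragment;
    * vs other genome: the k SNP bases (minus errors that happen to convert a
      SNP base into the other genome's allele, probability ``error_rate/3``
      each) plus the shared non-SNP errors.

    Columns: ``fragment_id, gene_id, true_origin, n_snps, mm_bd, mm_bs``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = rng.poisson(frag_snp_lambda, size=n)
    k = np.minimum(k, frag_len)
    origin_bd = rng.random(n) < 0.5

    shared_err = rng.binomial(frag_len - k, error_rate)
    err_at_snp = rng.binomial(k, error_rate)          # mismatch vs own genome
    err_to_other = rng.binomial(err_at_snp, 1.0 / 3)  # lands on other allele

    mm_own = shared_err + err_at_snp
    mm_other = shared_err + (k - err_to_other)

    mm_bd = np.where(origin_bd, mm_own, mm_other)
    mm_bs = np.where(origin_bd, mm_other, mm_own)
    frag = pd.DataFrame(
        {
            "fragment_id": [f"frag{i:07d}" for i in range(n)],
            "gene_id": gene_ids if gene_ids is not None else "NA",
            "true_origin": np.where(origin_bd, "Bd", "Bs"),
            "n_snps": k,
            "mm_bd": mm_bd,
            "mm_bs": mm_bs,
        }
    )
    return frag


# ---------------------------------------------------------------------------
# gene truth and counts
# ---------------------------------------------------------------------------

def _category_ratios(category: str, fold: float, sign: int) -> dict[str, float]:
    """Per-channel baseline multipliers implementing one HEB category.

    ``sign=+1`` places the larger copy on P1/Bd; ``-1`` flips the direction.
    The autotetraploid always mirrors P1 (its genome is an exact doubling).
    """
    hi, lo = (fold, 1.0) if sign > 0 else (1.0, fold)
    table = {
        "balance_retention": (1.0, 1.0, 1.0, 1.0),
        "bias_retention": (hi, lo, hi, lo),
        "bias_gain": (1.0, 1.0, hi, lo),
        "bias_loss": (hi, lo, 1.0, 1.0),
        "bias_switch": (hi, lo, lo, hi),
    }
    p1, p2, bd, bs = table[category]
    return {"P1": p1, "P2": p2, "BdSub": bd, "BsSub": bs, "Auto": p1}


def make_gene_truth(
    design: SimDesign,
    frac_rhythmic: float = 0.3,
    amplitude_range: tuple[float, float] = (0.5, 1.0),
    dispersion: float = 0.05,
    base_range: tuple[float, float] = (100.0, 2000.0),
    bias_fold: float = 2.0,
    category_probs: dict[str, float] | None = None,
    diploid_phase_gap_sd: float = 4.0,
    subgenome_phase_gap_sd: float = 1.0,
) -> pd.DataFrame:
    """Draw the planted per-gene truth table.

    Baselines are log-uniform over ``base_range`` (expected counts at a
    library of 1e6); each gene gets one of the five HEB categories (uniform
    unless ``category_probs`` is given) enforced as a ``bias_fold`` ratio on
    the relevant channel pair, a random bias direction, an NB dispersion, and
    — for the rhythmic fraction — an amplitude, a base peak phase, and
    per-channel phases.  Progenitor phases diverge with gap SD
    ``diploid_phase_gap_sd`` hours while the two subgenome phases are pulled
    together (gap SD ``subgenome_phase_gap_sd``), emulating the averaging of
    *trans*-acting inputs the hybrid genome brings together.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 11]))
    n = design.n_genes
    cats = list(HEB_CATEGORIES)
    if category_probs is None:
        p = np.full(len(cats), 1.0 / len(cats))
    else:
        p = np.array([category_probs.get(c, 0.0) for c in cats], dtype=float)
        p = p / p.sum()
    category = rng.choice(cats, size=n, p=p)
    sign = rng.choice([-1, 1], size=n)
    base = np.exp(rng.uniform(np.log(base_range[0]), np.log(base_range[1]), size=n))
    rhythmic = rng.random(n) < frac_rhythmic
    amplitude = np.where(
        rhythmic, rng.uniform(amplitude_range[0], amplitude_range[1], size=n), 0.0
    )
    phase = rng.uniform(0.0, 24.0, size=n)
    gap_dip = rng.normal(0.0, diploid_phase_gap_sd, size=n)
    gap_sub = rng.normal(0.0, subgenome_phase_gap_sd, size=n)

    truth = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n)],
            "category": category,
            "bias_sign": sign,
            "base": base,
            "dispersion": dispersion,
            "rhythmic": rhythmic,
            "amplitude": amplitude,
            "phase": phase,
            "phase_P1": (phase - gap_dip / 2) % 24.0,
            "phase_P2": (phase + gap_dip / 2) % 24.0,
            "phase_BdSub": (phase - gap_sub / 2) % 24.0,
            "phase_BsSub": (phase + gap_sub / 2) % 24.0,
        }
    )
    truth["phase_Auto"] = truth["phase_P1"]
    for ch in CHANNELS:
        truth[f"mu_{ch}"] = base * np.array(
            [_category_ratios(c, bias_fold, s)[ch] for c, s in zip(category, sign)]
        )
    return truth


def draw_library_sizes(design: SimDesign, seed: int | None = None) -> pd.Series:
    """Log-uniform per-sample mapped-read totals in [0.8, 1.2] x 1e7.

    The two subgenome channels are read fractions of one allopolyploid
    library, so each ``BsSub`` sample shares its mapped total with the
    matching ``BdSub`` sample (per-sample RPM denominators are the
    allopolyploid's totals in both subgenomes).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed if seed is None else seed, 13])
    )
    samples = []
    for ch in CHANNELS:
        for t in design.time_points_h:
            for r in range(1, design.n_replicates + 1):
                samples.append(f"{ch}_t{int(t):02d}_r{r}")
    sizes = np.exp(rng.uniform(np.log(0.8e7), np.log(1.2e7), size=len(samples)))
    out = pd.Series(np.round(sizes).astype(int), index=samples, name="mapped_total")
    for sid in out.index:
        if sid.startswith("BsSub_"):
            out[sid] = out[sid.replace("BsSub", "BdSub")]
    return out


def simulate_diel_counts(
    design: SimDesign,
    truth: pd.DataFrame,
    library_sizes: pd.Series,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw NB diurnal count matrices for every channel.

    The mean for gene g in channel c at clock hour t is::

        mu = baseline_{g,c} * (1 + A_g * cos(2*pi*(t - phase_{g,c}) / 24))
             * library_size_s / 1e6

    with variance ``mu + alpha_g * mu**2``.  Amplitudes above 1 would produce
    negative means and raise.  Returns ``(counts, meta)``: one genes x samples
    integer matrix per channel, and a sample-metadata table with columns
    ``sample_id, cytotype, clock_hour, replicate``.
    """
    if (truth["amplitude"] > 1.0).any():
        raise ValueError("amplitude > 1 would give a negative mean")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed if seed is None else seed, 17])
    )
    tp = np.asarray(design.time_points_h)
    amp = truth["amplitude"].to_numpy()[:, None]
    alpha = truth["dispersion"].to_numpy()
    counts: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for ch in CHANNELS:
        mu_base = truth[f"mu_{ch}"].to_numpy()[:, None]
        ph = truth[f"phase_{ch}"].to_numpy()[:, None]
        mu_t = mu_base * (1.0 + amp * np.cos(2 * np.pi * (tp[None, :] - ph) / 24.0))
        cols = {}
        for j, t in enumerate(tp):
            for r in range(1, design.n_replicates + 1):
                sid = f"{ch}_t{int(t):02d}_r{r}"
                lib = library_sizes[sid]
                mu = mu_t[:, j] * (lib / 1e6)
                cols[sid] = _nb_draw(rng, mu, alpha)
                meta_rows.append(
                    {"sample_id": sid, "cytotype": ch, "clock_hour": float(t),
                     "replicate": r}
                )
        counts[ch] = pd.DataFrame(cols, index=truth["gene_id"].to_numpy())
        counts[ch].index.name = "gene_id"
    meta = pd.DataFrame(meta_rows).drop_duplicates("sample_id").reset_index(drop=True)
    return counts, meta


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, var mu + alpha*mu^2) draws; Poisson when alpha ~ 0."""
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    if big.any():
        r = 1.0 / alpha[big]
        p = r / (r + mu[big])
        out[big] = rng.negative_binomial(r, p)
    return out


# ---------------------------------------------------------------------------
# bundle assembly and output
# ---------------------------------------------------------------------------

def generate_bundle(
    design: SimDesign,
    genome_length: int = 20_000,
    genome_snp_rate: float = 0.01,
    pileup_depth: int = 30,
    pileup_error_rate: float = 0.0,
    n_fragments: int = 10_000,
    frag_snp_lambda: float = 1.5,
    frag_error_rate: float = 0.005,
    **truth_kwargs,
) -> SimBundle:
    """Run every generator with streams derived from ``design.seed``."""
    ss = np.random.SeedSequence(design.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    reference, diverged, snps = generate_parental_genomes(
        genome_length, genome_snp_rate, seeds[0]
    )
    pileups = simulate_pileups(reference, snps, pileup_depth, pileup_error_rate, seeds[1])
    truth = make_gene_truth(design, **truth_kwargs)
    rng = np.random.default_rng(seeds[2])
    gene_ids = rng.choice(truth["gene_id"].to_numpy(), size=n_fragments)
    fragments = simulate_fragments(
        n_fragments, frag_snp_lambda, frag_error_rate, seeds[2], gene_ids=gene_ids
    )
    library_sizes = draw_library_sizes(design)
    counts, meta = simulate_diel_counts(design, truth, library_sizes)
    return SimBundle(
        design=design,
        reference=reference,
        diverged=diverged,
        snps=snps,
        pileups=pileups,
        fragments=fragments,
        truth=truth,
        counts=counts,
        meta=meta,
        library_sizes=library_sizes,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Write every artefact as plain text (FASTA + TSV) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .virtual_genome import write_fasta

    write_fasta({"chr1": bundle.reference}, outdir / "reference.fasta")
    write_fasta({"chr1": bundle.diverged}, outdir / "diverged.fasta")
    bundle.snps.to_csv(outdir / "snps_truth.tsv", sep="\t", index=False)
    bundle.pileups.to_csv(outdir / "pileups.tsv", sep="\t", index=False)
    bundle.fragments.to_csv(outdir / "fragments.tsv", sep="\t", index=False)
    bundle.truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    for ch, mat in bundle.counts.items():
        mat.to_csv(outdir / f"counts_{ch}.tsv", sep="\t")
    bundle.meta.merge(
        bundle.library_sizes.rename("mapped_total"),
        left_on="sample_id", right_index=True,
    ).to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
    design = dataclasses.asdict(bundle.design)
    design["time_points_h"] = list(design["time_points_h"])
    (outdir / "design.json").write_text(json.dumps(design, indent=2))
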