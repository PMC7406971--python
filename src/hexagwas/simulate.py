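"""Hexasomic-inheritance F1 population simulator.

Emulates the mapping design of a nulliplex x duplex sex-locus cross in an
autohexaploid: six homologs per parent, bivalent pairing at meiosis, three
homologs transmitted per gamete, ddRAD-like overdispersed read depths, and
phenotypes driven by a major sex-locus dosage effect plus recessive modifier
loci plus a polygenic background.

The simulator is the test bed for the whole analysis stack: every downstream
module (genotyping, distortion, heritability, association, LD) is validated
against populations generated here, where the truth is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PLOIDY = 6
GAMETE_SIZE = 3
N_YEARS = 5

__all__ = [
    "CrossConfig",
    "ReadModel",
    "PhenoModel",
    "Population",
    "random_cross",
    "simulate_gamete",
    "simulate_progeny",
    "simulate_reads",
    "simulate_phenotypes",
    "simulate_population",
    "write_population",
    "expected_f1_frequencies",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CrossConfig:
    """A single biparental cross with per-marker parental alt-allele dosages.

    ``maternal_dosage``/``paternal_dosage`` give the number of homologs
    (0..6) carrying the alternative allele at each marker.  The sex locus is
    constrained to a nulliplex mother and duplex father (XXXXXX x XXXXYY).
    """

    n_progeny: int
    markers: pd.DataFrame  # columns: chrom, pos (1-based), sorted
    maternal_dosage: np.ndarray
    paternal_dosage: np.ndarray
    chrom_lengths: list[tuple[str, int]]
    sex_locus: tuple[str, int] | None = None
    recomb_rate: float = 2.5  # cM per Mb
    double_reduction_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.maternal_dosage = np.asarray(self.maternal_dosage, dtype=int)
        self.paternal_dosage = np.asarray(self.paternal_dosage, dtype=int)
        m = len(self.markers)
        if len(self.maternal_dosage) != m or len(self.paternal_dosage) != m:
            raise ValueError("dosage vectors must match the marker count")
        for d in (self.maternal_dosage, self.paternal_dosage):
            if d.min() < 0 or d.max() > PLOIDY:
                raise ValueError("parental dosages must lie in 0..6")
        if not 0.0 <= self.double_reduction_rate <= 1.0:
            raise ValueError("double_reduction_rate must lie in [0, 1]")
        if self.sex_locus is not None:
            i = self.marker_index(*self.sex_locus)
            if self.maternal_dosage[i] != 0 or self.paternal_dosage[i] != 2:
                raise ValueError(
                    "sex locus must be nulliplex in the mother and duplex in the father"
                )

    def marker_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.markers["chrom"].values == chrom) & (self.markers["pos"].values == pos)
        )
        if hit.size == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hit[0])


@dataclass
class ReadModel:
    """ddRAD-like read-depth model: negative-binomial depth, binomial alt count."""

    mean_depth: float = 80.0
    depth_dispersion: float = 8.0  # NB size parameter; variance = mu + mu^2/size
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")


@dataclass
class PhenoModel:
    """Latent-scale phenotype model for male conversion.

    latent = intercept + beta_ogi * d_sex + sum_k effect_k * 1[d_k == 0]
             + polygenic + noise

    ``h2_poly`` is the polygenic fraction of the non-major-locus variance:
    sd(polygenic) = noise_sd * sqrt(h2_poly / (1 - h2_poly)).  The link maps
    the latent value to a conversion rate in [0, 1]; "logistic" is a shifted
    sigmoid, max(0, 2*sigmoid(x) - 1), so non-positive latent values give a
    rate of exactly 0 (trees that never convert), and "clamped-linear" is
    clip(x, 0, 1).  Ability is derived from the rate (1 iff rate > 0).
    """

    beta_ogi: float = 1.7
    modifier_loci: Sequence[tuple[str, int, float]] = field(default_factory=list)
    h2_poly: float = 0.2
    noise_sd: float = 0.55
    intercept: float = -2.4
    link: str = "logistic"
    year_shifts: tuple[float, ...] = (-0.30, -0.05, 0.10, 0.25, 0.35)
    year_noise_sd: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_poly < 1.0:
            raise ValueError("h2_poly must lie in [0, 1)")
        if self.link not in ("logistic", "clamped-linear"):
            raise ValueError("link must be 'logistic' or 'clamped-linear'")
        if len(self.year_shifts) != N_YEARS:
            raise ValueError(f"year_shifts must have length {N_YEARS}")


@dataclass
class Population:
    """A fully simulated population: truth, reads, phenotypes."""

    cross: CrossConfig
    markers: pd.DataFrame
    progeny_ids: list[str]
    parent_ids: tuple[str, str]
    dosage: np.ndarray          # (m, n_progeny) true progeny alt dosage 0..6
    ref_depth: np.ndarray       # (m, n_progeny)
    alt_depth: np.ndarray
    parent_ref_depth: np.ndarray  # (m, 2) mother, father
    parent_alt_depth: np.ndarray
    phenotypes: pd.DataFrame
    segments: dict | None = None


# ---------------------------------------------------------------------------
# gamete / progeny simulation
# ---------------------------------------------------------------------------

def simulate_gamete(
    parent_dosage: int | np.ndarray,
    double_reduction_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    size: int | None = None,
) -> np.ndarray | int:
    """Draw gamete alt-allele counts (0..3) at a single unlinked marker.

    With no double reduction the count is hypergeometric: 3 of the parent's
    6 homologs sampled without replacement, ``parent_dosage`` of which carry
    the alt allele.  With double reduction, a gamete occasionally receives
    two sister copies of one homolog plus one other homolog.
    """
    rng = np.random.default_rng() if rng is None else rng
    d = np.asarray(parent_dosage)
    if np.any((d < 0) | (d > PLOIDY)):
        raise ValueError("parent_dosage must lie in 0..6")
    scalar = d.ndim == 0 and size is None
    n = 1 if scalar else (size if size is not None else d.shape[0])
    d = np.broadcast_to(d, (n,))
    counts = rng.hypergeometric(d, PLOIDY - d, GAMETE_SIZE)
    if double_reduction_rate > 0:
        dr = rng.random(n) < double_reduction_rate
        if dr.any():
            k = int(dr.sum())
            dd = d[dr]
            # two distinct homologs; one transmitted twice
            dup = rng.hypergeometric(dd, PLOIDY - dd, 1).ravel()
            other = rng.hypergeometric(dd - dup, PLOIDY - 1 - (dd - dup), 1).ravel()
            counts[dr] = 2 * dup + other
    return int(counts[0]) if scalar else counts


def _assign_homologs(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Assign alt alleles to a random subset of the 6 homologs per marker.

    Returns a boolean (6, m) matrix with column sums equal to ``dosage``.
    """
    m = dosage.shape[0]
    # random permutation of homolog ranks per marker; alt on the lowest d ranks
    ranks = np.argsort(rng.random((PLOIDY, m)), axis=0)
    return ranks < dosage[None, :]


def _meiosis_chromatids(
    positions: np.ndarray,
    length_bp: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list]:
    """One meiosis: pair the 6 homologs into 3 bivalents and transmit one
    recombinant chromatid per pair.

    Returns a (3, m) array of homolog indices (0..5) at each marker position
    plus a compact segment description.
    """
    perm = rng.permutation(PLOIDY)
    morgans = recomb_rate * length_bp / 1e6 / 100.0
    idx = np.empty((GAMETE_SIZE, positions.shape[0]), dtype=np.int8)
    segmap = []
    for p in range(GAMETE_SIZE):
        pair = perm[2 * p : 2 * p + 2]
        n_xo = rng.poisson(morgans)
        xo = np.sort(rng.uniform(0, length_bp, n_xo)) if n_xo else np.empty(0)
        start = rng.integers(2)
        phase = (start + np.searchsorted(xo, positions)) % 2
        idx[p] = pair[phase]
        segmap.append((tuple(int(h) for h in pair), int(start), xo.tolist()))
    return idx, segmap


def simulate_progeny(
    cross: CrossConfig,
    rng: np.random.Generator | None = None,
    keep_segments: bool = False,
) -> tuple[np.ndarray, dict]:
    """Simulate true progeny dosages (m, n_progeny) under hexasomic meiosis.

    Markers on a chromosome co-inherit through shared homolog segments;
    crossovers occur at ``recomb_rate`` cM/Mb.  Each progeny dosage is the
    sum of a maternal and a paternal gamete (each 0..3 alt copies).
    """
    rng = np.random.default_rng(cross.seed) if rng is None else rng
    m = len(cross.markers)
    chroms = cross.markers["chrom"].values
    pos = cross.markers["pos"].values.astype(float)
    lengths = dict(cross.chrom_lengths)

    hap = {
        "mother": _assign_homologs(cross.maternal_dosage, rng),
        "father": _assign_homologs(cross.paternal_dosage, rng),
    }
    dosage = np.zeros((m, cross.n_progeny), dtype=np.int8)
    segments: dict = {}

    chrom_slices = []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        chrom_slices.append((chrom, sel, pos[sel], lengths[chrom]))

    dr = cross.double_reduction_rate
    for j in range(cross.n_progeny):
        for parent in ("mother", "father"):
            H = hap[parent]
            for chrom, sel, cpos, clen in chrom_slices:
                idx, segmap = _meiosis_chromatids(cpos, clen, cross.recomb_rate, rng)
                if dr > 0:
                    for p in range(GAMETE_SIZE):
                        if rng.random() < dr:
                            # double reduction: this slot carries two copies of
                            # another pair's chromatid instead of its own
                            src = rng.integers(GAMETE_SIZE - 1)
                            src = src if src < p else src + 1
                            idx[p] = idx[src]
                alleles = H[:, sel][idx, np.arange(sel.size)[None, :]]
                dosage[sel, j] += alleles.sum(axis=0).astype(np.int8)
                if keep_segments:
                    segments[(j, parent, chrom)] = segmap
    return dosage, segments


def expected_f1_frequencies() -> np.ndarray:
    """Expected F1 alt-allele frequencies over all parental dosage pairs.

    Each gamete transmits on average d/2 of its parent's alt copies, so the
    expected progeny frequency is (d_mat + d_pat)/12; over all pairs the sums
    0..12 give exactly 13 distinct values.
    """
    vals = {
        (d1 + d2) / (2 * PLOIDY)
        for d1 in range(PLOIDY + 1)
        for d2 in range(PLOIDY + 1)
    }
    return np.array(sorted(vals))


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    true_dosage: np.ndarray,
    model: ReadModel,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (ref_count, alt_count) for an array of true dosages 0..6.

    Total depth is negative-binomial with mean ``mean_depth``; each read
    reports the alt allele with probability (d/6)(1-e) + (1-d/6)e.
    """
    rng = np.random.default_rng() if rng is None else rng
    d = np.asarray(true_dosage)
    size = model.depth_dispersion
    p_nb = size / (size + model.mean_depth)
    depth = rng.negative_binomial(size, p_nb, d.shape)
    frac = d / PLOIDY
    p_alt = frac * (1 - model.error_rate) + (1 - frac) * model.error_rate
    alt = rng.binomial(depth, p_alt)
    return depth - alt, alt


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _link(latent: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return np.maximum(0.0, 2.0 / (1.0 + np.exp(-latent)) - 1.0)
    return np.clip(latent, 0.0, 1.0)


def simulate_phenotypes(
    dosage: np.ndarray,
    cross: CrossConfig,
    model: PhenoModel,
    rng: np.random.Generator | None = None,
    progeny_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate per-year and cumulative male-conversion phenotypes.

    Returns a table with individual_id, ability_cumulative, rate_y1..y5,
    rate_cumulative, plus the underlying ``latent`` value (useful for
    variance-component studies on an unclamped scale).
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = dosage.shape[1]
    latent = np.full(n, model.intercept, dtype=float)

    if model.beta_ogi != 0.0:
        if cross.sex_locus is None:
            raise ValueError("beta_ogi != 0 requires a sex locus in the cross")
        latent += model.beta_ogi * dosage[cross.marker_index(*cross.sex_locus)]

    for chrom, pos, effect in model.modifier_loci:
        try:
            k = cross.marker_index(chrom, pos)
        except KeyError as err:
            raise ValueError(f"modifier locus {chrom}:{pos} not in marker map") from err
        latent += effect * (dosage[k] == 0)

    if model.h2_poly > 0:
        centered = dosage - dosage.mean(axis=1, keepdims=True)
        b = rng.normal(size=dosage.shape[0])
        g = centered.T @ b
        sd = g.std()
        target = model.noise_sd * math.sqrt(model.h2_poly / (1 - model.h2_poly))
        if sd > 0:
            latent += g * (target / sd)
    if model.noise_sd > 0:
        latent += rng.normal(0.0, model.noise_sd, n)

    rates = np.empty((N_YEARS, n))
    for t in range(N_YEARS):
        yearly = latent + model.year_shifts[t]
        if model.year_noise_sd > 0:
            yearly = yearly + rng.normal(0.0, model.year_noise_sd, n)
        rates[t] = _link(yearly, model.link)
    rate_cum = rates.mean(axis=0)
    ability = (rate_cum > 0).astype(int)

    ids = list(progeny_ids) if progeny_ids is not None else [f"F1_{j:03d}" for j in range(n)]
    out = {"individual_id": ids, "ability_cumulative": ability}
    for t in range(N_YEARS):
        out[f"rate_y{t + 1}"] = rates[t]
    out["rate_cumulative"] = rate_cum
    out["latent"] = latent
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# whole-population convenience + factory
# ---------------------------------------------------------------------------

def random_cross(
    n_progeny: int = 83,
    chrom_lengths: Sequence[tuple[str, int]] | None = None,
    n_markers_per_chrom: int = 200,
    sex_locus: tuple[str, int] | None = ("chr01", 17_052_751),
    modifier_loci: Sequence[tuple[str, int]] = (),
    recomb_rate: float = 2.5,
    double_reduction_rate: float = 0.0,
    seed: int = 0,
) -> CrossConfig:
    """Build a CrossConfig with random parental dosages spanning 0..6.

    The sex locus (if any) is forced to maternal 0 / paternal 2; modifier
    loci are forced to simplex x simplex so nulliplex progeny segregate.
    """
    if chrom_lengths is None:
        chrom_lengths = [(f"chr{c:02d}", 20_000_000) for c in range(1, 6)]
    rng = np.random.default_rng(seed)
    rows, mat, pat = [], [], []
    forced = {}
    if sex_locus is not None:
        forced[sex_locus] = (0, 2)
    for chrom, pos in modifier_loci:
        if (chrom, pos) in forced:
            raise ValueError("modifier locus collides with the sex locus")
        forced[(chrom, pos)] = (1, 1)
    chrom_names = [c for c, _ in chrom_lengths]
    for chrom, length in chrom_lengths:
        pos = np.sort(rng.choice(np.arange(1, length + 1), n_markers_per_chrom, replace=False))
        for p in pos:
            rows.append((chrom, int(p)))
            mat.append(rng.integers(0, PLOIDY + 1))
            pat.append(rng.integers(0, PLOIDY + 1))
    for (chrom, pos), (dm, dp) in forced.items():
        if chrom not in chrom_names:
            raise ValueError(f"locus chromosome {chrom} not in chrom_lengths")
        rows.append((chrom, int(pos)))
        mat.append(dm)
        pat.append(dp)
    markers = pd.DataFrame(rows, columns=["chrom", "pos"])
    order = np.lexsort((markers["pos"].values, markers["chrom"].values))
    markers = markers.iloc[order].reset_index(drop=True)
    if markers.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate marker positions; use a different seed")
    return CrossConfig(
        n_progeny=n_progeny,
        markers=markers,
        maternal_dosage=np.array(mat)[order],
        paternal_dosage=np.array(pat)[order],
        chrom_lengths=list(chrom_lengths),
        sex_locus=sex_locus,
        recomb_rate=recomb_rate,
        double_reduction_rate=double_reduction_rate,
        seed=seed,
    )


def simulate_population(
    cross: CrossConfig,
    read_model: ReadModel | None = None,
    pheno_model: PhenoModel | None = None,
    keep_segments: bool = False,
) -> Population:
    """Simulate genotypes, reads and phenotypes for a cross in one call.

    The cross seed is expanded into independent substreams for meiosis,
    reads and phenotypes so each stage is separately reproducible.
    """
    read_model = read_model or ReadModel()
    pheno_model = pheno_model or PhenoModel()
    ss = np.random.SeedSequence(cross.seed)
    rng_meio, rng_read, rng_pheno = (np.random.default_rng(s) for s in ss.spawn(3))

    dosage, segments = simulate_progeny(cross, rng=rng_meio, keep_segments=keep_segments)
    ref, alt = simulate_reads(dosage, read_model, rng=rng_read)
    pref, palt = simulate_reads(
        np.stack([cross.maternal_dosage, cross.paternal_dosage], axis=1),
        read_model,
        rng=rng_read,
    )
    pheno = simulate_phenotypes(dosage, cross, pheno_model, rng=rng_pheno)
    return Population(
        cross=cross,
        markers=cross.markers,
        progeny_ids=list(pheno["individual_id"]),
        parent_ids=("mother", "father"),
        dosage=dosage,
        ref_depth=ref,
        alt_depth=alt,
        parent_ref_depth=pref,
        parent_alt_depth=palt,
        phenotypes=pheno,
        segments=segments if keep_segments else None,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_population(
    pop: Population,
    vcf_path: str | Path,
    pheno_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Write VCF (AD per genotype, parents first), phenotype TSV, truth TSV."""
    vcf_path, pheno_path, truth_path = Path(vcf_path), Path(pheno_path), Path(truth_path)
    samples = list(pop.parent_ids) + pop.progeny_ids
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hexagwas-simulator\n")
        for chrom, length in pop.cross.chrom_lengths:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        m = len(pop.markers)
        chroms = pop.markers["chrom"].values
        positions = pop.markers["pos"].values
        for i in range(m):
            fields = [
                str(chroms[i]), str(positions[i]), f"m{i:06d}", "A", "T",
                ".", "PASS", ".", "GT:AD",
            ]
            cols = [
                f"./.:{pop.parent_ref_depth[i, 0]},{pop.parent_alt_depth[i, 0]}",
                f"./.:{pop.parent_ref_depth[i, 1]},{pop.parent_alt_depth[i, 1]}",
            ]
            cols += [
                f"./.:{pop.ref_depth[i, j]},{pop.alt_depth[i, j]}"
                for j in range(len(pop.progeny_ids))
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(cols) + "\n")

    pheno_cols = ["individual_id", "ability_cumulative"] + [
        f"rate_y{t + 1}" for t in range(N_YEARS)
    ] + ["rate_cumulative"]
    pop.phenotypes[pheno_cols].to_csv(pheno_path, sep="\t", index=False, float_format="%.6g")

    truth = pop.markers.copy()
    truth["maternal_dosage"] = pop.cross.maternal_dosage
    truth["paternal_dosage"] = pop.cross.paternal_dosage
    for j, name in enumerate(pop.progeny_ids):
        truth[name] = pop.dosage[:, j]
    truth.to_csv(truth_path, sep="\t", index=False)
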