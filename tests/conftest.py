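import numpy as np
import pytest

from hexagwas import genotypes as gt
from hexagwas import simulate as sim


def ad_from_pop(pop, min_depth: int = 20) -> gt.AlleleDepthMatrix:
    """AlleleDepthMatrix for the progeny of a simulated population."""
    total = pop.ref_depth + pop.alt_depth
    return gt.AlleleDepthMatrix(
        markers=pop.markers.assign(ref="A", alt="T"),
        individuals=list(pop.progeny_ids),
        ref_depth=pop.ref_depth,
        alt_depth=pop.alt_depth,
        missing=total <= min_depth,
    )


def filtered_diploidized(pop, min_depth: int = 20):
    """Diploidized matrix after the standard MAF/missingness filter."""
    q = gt.allele_ratio(ad_from_pop(pop, min_depth))
    dip = gt.DiploidizedMatrix(q.markers, list(pop.progeny_ids), gt.diploidize(q.ratio))
    keep = gt.filter_markers(dip)
    idx = np.flatnonzero(keep)
    return gt.DiploidizedMatrix(
        dip.markers.iloc[idx].reset_index(drop=True), dip.individuals, dip.geno[idx]
    ), q


@pytest.fixture(scope="session")
def small_pop():
    cross = sim.random_cross(n_progeny=60, n_markers_per_chrom=80, seed=11)
    return sim.simulate_population(cross)


@pytest.fixture(scope="session")
def pop_files(small_pop, tmp_path_factory):
    d = tmp_path_factory.mktemp("pop")
    paths = (d / "pop.vcf", d / "pheno.tsv", d / "truth.tsv")
    sim.write_population(small_pop, *paths)
    return paths
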