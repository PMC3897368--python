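"""Peak classification, CpG association, densities, metagene profiles."""
import numpy as np
import pandas as pd
import pytest

from h3k4diff import (CoverageTrack, GenomeAnnotation,
                      MappingError, Peak, PeakSet, UndefinedStatisticError,
                      chromosome_distribution, classify_peaks, cpg_association,
                      metagene_profile)


def make_peak(chrom, summit, name="p", half=175):
    return Peak(chrom=chrom, start=summit - half, end=summit + half, name=name,
                summit=summit, amplitude=30.0, p_value=1e-10, score=100.0)


@pytest.fixture(scope="module")
def toy_annotation():
    genes = pd.DataFrame([
        dict(gene_id="gA", chrom="chr1", strand="+", start=50_000, end=60_000),
        dict(gene_id="gB", chrom="chr1", strand="-", start=80_000, end=95_000),
    ])
    islands = pd.DataFrame([dict(chrom="chr1", start=49_500, end=50_500)])
    return GenomeAnnotation(chrom_lengths={"chr1": 200_000}, genes=genes,
                            cpg_islands=islands)


@pytest.mark.parametrize("summit, expected", [
    (49_500, "upstream"),     # 500 bp 5' of the + strand TSS
    (55_000, "intragenic"),   # mid-gene
    (61_500, "downstream"),   # 1.5 kb 3' of the + strand TES
    (96_500, "upstream"),     # 1.5 kb 5' of the - strand TSS (right of gene)
    (78_500, "downstream"),   # 1.5 kb 3' of the - strand TES (left of gene)
    (20_000, "intergenic"),   # far from everything
    (63_000, "intergenic"),   # 3 kb from gA, 17 kb from gB
])
def test_classification_rule_instances(toy_annotation, summit, expected):
    classified, _ = classify_peaks(PeakSet([make_peak("chr1", summit)]),
                                   toy_annotation)
    assert classified[0].category == expected


def test_fractions_sum_to_one(study_sim):
    _, fractions = classify_peaks(study_sim.peaks_wt, study_sim.annotation)
    assert abs(sum(fractions.values()) - 1.0) < 1e-9


def test_unknown_chromosome_raises(toy_annotation):
    with pytest.raises(MappingError, match="chrM"):
        classify_peaks(PeakSet([make_peak("chrM", 1000)]), toy_annotation)


# ---------------------------------------------------------------------------
# quadratic-scan oracle
# ---------------------------------------------------------------------------

def oracle_classify(peak, genes, up=2000, down=2000, inter=2000):
    """Independent brute-force classifier scanning every gene, vectorized."""
    if len(genes) == 0:
        return "intergenic"
    s = peak.summit
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    tss = genes["tss"].to_numpy()
    tes = genes["tes"].to_numpy()
    plus = (genes["strand"] == "+").to_numpy()
    upstream = np.where(plus, (tss - up <= s) & (s <= tss - 1),
                        (tss + 1 <= s) & (s <= tss + up))
    inside = (start <= s) & (s < end)
    downstream = np.where(plus, (tes + 1 <= s) & (s <= tes + down),
                          (tes - down <= s) & (s <= tes - 1))
    if upstream.any():
        return "upstream"
    if inside.any():
        return "intragenic"
    if downstream.any():
        return "downstream"
    gap = np.where((peak.start < end) & (start < peak.end), 0,
                   np.where(peak.end <= start, start - (peak.end - 1),
                            peak.start - (end - 1)))
    if gap.min() >= inter:
        return "intergenic"
    dist = np.where(inside, 0, np.where(s < start, start - s, s - (end - 1)))
    g = int(np.argmin(dist))
    if start[g] <= s < end[g]:
        return "intragenic"
    return "upstream" if (s < start[g]) == plus[g] else "downstream"


def random_peaks(annotation, n, rng):
    peaks = []
    chroms = list(annotation.chrom_lengths)
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = annotation.chrom_lengths[chrom]
        half = int(rng.integers(50, 400))
        summit = int(rng.integers(half, length - half))
        peaks.append(make_peak(chrom, summit, name=f"r{i}", half=half))
    return PeakSet(peaks)


def test_classification_matches_quadratic_oracle(study_sim):
    rng = np.random.default_rng(2024)
    peaks = random_peaks(study_sim.annotation, 600, rng)
    classified, _ = classify_peaks(peaks, study_sim.annotation)
    genes = study_sim.annotation.genes
    for p in classified:
        g = genes[genes["chrom"] == p.chrom]
        assert p.category == oracle_classify(p, g), p.name


# ---------------------------------------------------------------------------
# CpG association
# ---------------------------------------------------------------------------

def test_cpg_trivial_fractions(toy_annotation):
    inside = PeakSet([make_peak("chr1", 50_000, "in", half=100)])
    outside = PeakSet([make_peak("chr1", 150_000, "out")])
    assert cpg_association(inside, toy_annotation.cpg_islands) == 100.0
    assert cpg_association(outside, toy_annotation.cpg_islands) == 0.0


def test_cpg_empty_filtered_set_is_undefined(toy_annotation):
    peaks, _ = classify_peaks(PeakSet([make_peak("chr1", 55_000)]),
                              toy_annotation)
    with pytest.raises(UndefinedStatisticError):
        cpg_association(peaks, toy_annotation.cpg_islands,
                        category_filter="intergenic")


def test_cpg_matches_planted_flags_exactly(study_sim):
    classified, _ = classify_peaks(study_sim.peaks_wt, study_sim.annotation)
    truth = study_sim.truth.peaks.set_index("name")
    flags = [bool(truth.loc[p.name, "cpg_flag"]) for p in classified]
    expected = round(100.0 * sum(flags) / len(flags), 1)
    assert cpg_association(classified, study_sim.annotation.cpg_islands) == expected
    inter_flags = [f for f, p in zip(flags, classified)
                   if p.category == "intergenic"]
    expected_inter = round(100.0 * sum(inter_flags) / len(inter_flags), 1)
    assert cpg_association(classified, study_sim.annotation.cpg_islands,
                           category_filter="intergenic") == expected_inter


def test_cpg_invariant_to_island_fragmentation_and_order(study_sim):
    classified, _ = classify_peaks(study_sim.peaks_wt, study_sim.annotation)
    islands = study_sim.annotation.cpg_islands
    baseline = cpg_association(classified, islands)
    mid = (islands["start"] + islands["end"]) // 2
    split = pd.concat([
        pd.DataFrame(dict(chrom=islands["chrom"], start=islands["start"], end=mid)),
        pd.DataFrame(dict(chrom=islands["chrom"], start=mid, end=islands["end"])),
    ]).sample(frac=1.0, random_state=0).reset_index(drop=True)
    assert cpg_association(classified, split) == baseline
    shuffled = PeakSet(list(classified)[::-1])
    assert cpg_association(shuffled, islands) == baseline


# ---------------------------------------------------------------------------
# chromosome distribution
# ---------------------------------------------------------------------------

def test_density_per_megabase(toy_annotation):
    peaks = PeakSet([make_peak("chr1", 10_000 + 1000 * i, f"d{i}")
                     for i in range(10)])
    dens = chromosome_distribution(peaks, {"chr1": 10_000_000, "chr2": 5_000_000})
    assert dens["chr1"] == pytest.approx(1.0)
    assert dens["chr2"] == 0.0


def test_density_requires_lengths_and_handles_empty():
    assert chromosome_distribution(PeakSet(), {"chr1": 1_000_000}) == {"chr1": 0.0}
    with pytest.raises(MappingError):
        chromosome_distribution(PeakSet([make_peak("chrX", 5000)]),
                                {"chr1": 1_000_000})


def test_uniform_placement_gives_equal_densities_within_poisson_bounds():
    rng = np.random.default_rng(77)
    lengths = {f"chr{i}": 5_000_000 for i in range(1, 5)}
    peaks = PeakSet([make_peak(f"chr{rng.integers(1, 5)}", int(rng.integers(1000, 4_999_000)), f"u{i}")
                     for i in range(400)])
    dens = chromosome_distribution(peaks, lengths)
    expected = 400 / 4 / 5.0  # peaks per Mb
    for d in dens.values():
        assert abs(d - expected) < 3 * np.sqrt(100) / 5.0


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------

def constant_track(lengths, c, step=50):
    return CoverageTrack(values={ch: np.full(int(np.ceil(l / step)), float(c))
                                 for ch, l in lengths.items()}, step=step)


def test_flat_signal_gives_flat_profile(study_sim):
    track = constant_track(study_sim.annotation.chrom_lengths, 7.0)
    prof = metagene_profile(track, study_sim.annotation, flank=5000,
                            n_body_bins=300)
    assert np.allclose(prof.concatenated(), 7.0)


def test_profile_is_linear_in_signal(study_sim):
    treatment, _ = study_sim.tracks["wt"]
    doubled = treatment.scaled(2.0)
    p1 = metagene_profile(treatment, study_sim.annotation)
    p2 = metagene_profile(doubled, study_sim.annotation)
    assert np.allclose(p2.concatenated(), 2.0 * p1.concatenated())


def test_tss_centred_landscape_peaks_at_the_tss(study_sim):
    treatment, _ = study_sim.tracks["wt"]
    prof = metagene_profile(treatment, study_sim.annotation, flank=5000,
                            n_body_bins=300)
    n_up = 5000 // treatment.step
    peak_index = int(np.argmax(prof.concatenated()))
    # planted promoter peaks sit 100-500 bp 5' of the TSS
    assert n_up - 15 <= peak_index <= n_up + 2


def test_mirrored_minus_strand_gene_gives_identical_profile():
    step = 50
    length = 200_000
    vals_plus = np.zeros(length // step)
    vals_minus = np.zeros(length // step)
    # + strand gene at [100k, 110k); signal bump 300 bp 5' of its TSS
    # - strand gene at [100k, 110k) on a mirrored chromosome: TSS at 110k-1
    vals_plus[(100_000 - 300) // step] = 50.0
    vals_minus[(109_999 + 300) // step] = 50.0
    genes_plus = pd.DataFrame([dict(gene_id="p", chrom="c", strand="+",
                                    start=100_000, end=110_000)])
    genes_minus = pd.DataFrame([dict(gene_id="m", chrom="c", strand="-",
                                     start=100_000, end=110_000)])
    prof_plus = metagene_profile(
        CoverageTrack(values={"c": vals_plus}, step=step),
        GenomeAnnotation({"c": length}, genes_plus), flank=5000, n_body_bins=200)
    prof_minus = metagene_profile(
        CoverageTrack(values={"c": vals_minus}, step=step),
        GenomeAnnotation({"c": length}, genes_minus), flank=5000, n_body_bins=200)
    assert np.allclose(prof_plus.concatenated(), prof_minus.concatenated())
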