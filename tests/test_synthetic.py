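"""Synthetic-landscape generator: determinism, planted structure, coverage."""
import numpy as np
import pytest
from scipy import stats

from h3k4diff import (CapacityError, EmptyTrackError, SimConfig,
                      generate_coverage_tracks, generate_expression_table,
                      generate_genome, generate_peak_landscapes,
                      preferential_enrichment, simulate)


def binom99(n: int, p: float) -> tuple[float, float]:
    lo, hi = stats.binom.interval(0.99, n, p)
    return lo / n, hi / n


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def test_gene_count_and_separation(small_sim, small_config):
    genes = small_sim.annotation.genes
    assert len(genes) == small_config.n_genes
    for chrom in small_sim.annotation.chrom_lengths:
        g = genes[genes["chrom"] == chrom].sort_values("start")
        gaps = g["start"].values[1:] - g["end"].values[:-1]
        assert (gaps >= 5000).all()


def test_same_seed_gives_byte_identical_bed(small_config):
    a = generate_genome(small_config)
    b = generate_genome(small_config)
    assert a.genes_bed() == b.genes_bed()
    assert a.islands_bed() == b.islands_bed()


def test_full_cpg_planting_covers_every_tss():
    cfg = SimConfig(n_genes=80, chrom_length=4_000_000, cpg_at_tss_fraction=1.0,
                    n_unique_wt=0, n_unique_ko=0, n_preferential_wt=0,
                    n_preferential_ko=0, seed=3)
    annotation = generate_genome(cfg)
    islands = annotation.cpg_islands
    for g in annotation.genes.itertuples():
        on_chrom = islands[islands["chrom"] == g.chrom]
        assert ((on_chrom["start"] <= g.tss) & (g.tss < on_chrom["end"])).any()


def test_overfull_genome_raises_capacity_error():
    cfg = SimConfig(n_genes=300, chrom_length=1_000_000, seed=1)
    with pytest.raises(CapacityError, match="n_genes|chrom_length"):
        generate_genome(cfg)


# ---------------------------------------------------------------------------
# peak landscapes
# ---------------------------------------------------------------------------

def test_planted_counts_match_config(study_sim, study_config):
    counts = study_sim.truth.status_counts()
    assert counts["unique_wt"] == study_config.n_unique_wt
    assert counts["unique_ko"] == study_config.n_unique_ko
    assert counts["preferential_wt"] == study_config.n_preferential_wt
    assert counts["preferential_ko"] == study_config.n_preferential_ko


def test_unique_planting_is_exact():
    cfg = SimConfig(n_genes=60, chrom_length=3_000_000, n_unique_wt=5,
                    n_unique_ko=0, n_preferential_wt=0, n_preferential_ko=0,
                    reads_per_condition=10_000, seed=11)
    annotation = generate_genome(cfg)
    peaks_wt, peaks_ko, truth = generate_peak_landscapes(annotation, cfg)
    planted = truth.gene_set("unique_wt")
    assert len(planted) == 5
    wt_names = {p.name for p in peaks_wt}
    ko_names = {p.name for p in peaks_ko}
    for gid in planted:
        assert f"up_{gid}" in wt_names
        assert f"up_{gid}" not in ko_names


def test_preferential_ratio_recoverable_from_emitted_peaks(tmp_path):
    from h3k4diff import PeakSet
    cfg = SimConfig(n_genes=80, chrom_length=4_000_000, preferential_fold=3.0,
                    n_unique_wt=0, n_unique_ko=0, n_preferential_wt=8,
                    n_preferential_ko=8, reads_per_condition=12_000, seed=11)
    annotation = generate_genome(cfg)
    peaks_wt, peaks_ko, truth = generate_peak_landscapes(annotation, cfg)
    # read amplitudes back from the serialized BED, as a consumer would
    peaks_wt.write_bed(tmp_path / "wt.bed")
    peaks_ko.write_bed(tmp_path / "ko.bed")
    amp_wt = {p.name: p.amplitude for p in PeakSet.read_bed(tmp_path / "wt.bed")}
    amp_ko = {p.name: p.amplitude for p in PeakSet.read_bed(tmp_path / "ko.bed")}
    jitter_band = (1.1 / 0.9) + 1e-9
    for status, hi_amp, lo_amp in (("preferential_wt", amp_wt, amp_ko),
                                   ("preferential_ko", amp_ko, amp_wt)):
        genes = truth.gene_set(status)
        assert len(genes) == 8
        for gid in genes:
            ratio = hi_amp[f"up_{gid}"] / lo_amp[f"up_{gid}"]
            assert 3.0 / jitter_band <= ratio <= 3.0 * jitter_band


def test_category_fractions_match_mix_within_binomial_bounds(study_sim,
                                                             study_config):
    cats = study_sim.truth.peaks["category"].value_counts()
    n = int(cats.sum())
    for cat, p in study_config.category_mix.items():
        lo, hi = binom99(n, p)
        assert lo <= cats.get(cat, 0) / n <= hi


def test_planted_peaks_lie_inside_chromosomes(study_sim, study_config):
    peaks = study_sim.truth.peaks
    assert (peaks["start"] >= 0).all()
    for chrom, length in study_config.chrom_lengths.items():
        assert (peaks.loc[peaks["chrom"] == chrom, "end"] <= length).all()


def test_planted_truth_is_self_consistent(study_sim):
    """Applying the published rules to the emitted peak sets reproduces the
    truth table exactly when amplitudes carry no jitter."""
    differential = preferential_enrichment(study_sim.peaks_wt,
                                           study_sim.peaks_ko,
                                           study_sim.annotation)
    for status in ("unique_wt", "unique_ko", "preferential_wt",
                   "preferential_ko"):
        recovered = {g for g, c in differential.items() if c.status == status}
        assert recovered == study_sim.truth.gene_set(status), status
    unchanged = {g for g, c in differential.items() if c.status == "unchanged"}
    assert unchanged == study_sim.truth.gene_set("both")


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def test_null_landscape_tracks_match_in_distribution():
    from h3k4diff import PeakSet
    cfg = SimConfig(n_genes=10, chrom_length=2_000_000,
                    n_unique_wt=0, n_unique_ko=0, n_preferential_wt=0,
                    n_preferential_ko=0, reads_per_condition=6_000, seed=5)
    treatment, control = generate_coverage_tracks(PeakSet(), cfg, "wt")
    t = treatment.values["chr1"]
    c = control.values["chr1"]
    hi = int(max(t.max(), c.max()))
    table = np.array([[np.sum(t == v) for v in range(hi + 1)],
                      [np.sum(c == v) for v in range(hi + 1)]])
    table = table[:, table.sum(axis=0) > 0]
    _, p, _, _ = stats.chi2_contingency(table)
    assert p > 0.001


def test_planted_peaks_tower_over_background(study_sim):
    treatment, _ = study_sim.tracks["wt"]
    vals = treatment.values["chr1"]
    step = treatment.step
    peak_bins = set()
    for p in study_sim.peaks_wt:
        peak_bins.update(range(p.start // step - 10, p.end // step + 10))
    background = np.delete(vals, [b for b in peak_bins if 0 <= b < vals.size])
    threshold = np.quantile(background, 0.999)
    for p in study_sim.peaks_wt:
        if p.amplitude >= 10:
            window = vals[p.start // step:(p.end - 1) // step + 1]
            assert window.max() >= threshold


def test_zero_reads_raise_empty_track_error(study_sim):
    cfg = SimConfig(reads_per_condition=0, seed=1)
    with pytest.raises(EmptyTrackError):
        generate_coverage_tracks(study_sim.peaks_wt, cfg, "wt")


def test_track_depth_metadata(study_sim, study_config):
    for geno in ("wt", "ko"):
        treatment, control = study_sim.tracks[geno]
        assert treatment.total_reads == study_config.reads_per_condition
        assert control.total_reads == study_config.reads_per_condition


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

def _n_passing(table):
    return int(((table["fold_change"] >= 1.5) & (table["p_value"] < 0.01)).sum())


@pytest.mark.parametrize("concordance", [0.0, 1.0])
def test_degenerate_concordance(concordance, small_config):
    cfg = SimConfig(**{**small_config.__dict__, "de_concordance": concordance})
    sim = simulate(cfg, with_coverage=False)
    n_diff = len(sim.truth.genes) - len(sim.truth.gene_set("both")) \
        - len(sim.truth.gene_set("neither"))
    assert _n_passing(sim.expression) == (0 if concordance == 0.0 else n_diff)


def test_concordance_fraction_within_binomial_bounds():
    cfg = SimConfig(n_genes=700, chrom_length=25_000_000, de_concordance=0.17,
                    n_unique_wt=120, n_unique_ko=120, n_preferential_wt=130,
                    n_preferential_ko=130, reads_per_condition=80_000, seed=13)
    annotation = generate_genome(cfg)
    _, _, truth = generate_peak_landscapes(annotation, cfg)
    table = generate_expression_table(truth, cfg)
    n_planted = 500
    lo, hi = binom99(n_planted, 0.17)
    assert lo <= _n_passing(table) / n_planted <= hi


def test_de_direction_matches_enrichment_direction(study_sim):
    truth = study_sim.truth
    expr = study_sim.expression.set_index("gene")
    for gid in truth.de_set("up_wt"):
        assert truth.genes.set_index("gene_id").loc[gid, "status"] in (
            "unique_wt", "preferential_wt")
        assert expr.loc[gid, "direction"] == "wt"
        assert expr.loc[gid, "fold_change"] >= 1.5
        assert expr.loc[gid, "p_value"] < 0.01
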