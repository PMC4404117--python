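"""Wright-Fisher selection simulator: determinism, drift, LD, hitchhiking."""

import numpy as np
import pandas as pd
import pytest

from splinewin import PoolSpec, SimConfig, emit_pooled_dataset, simulate_replicate
from splinewin.popgen import fst_array
from splinewin.simulate import FounderPool, build_genome, run_burnin, run_selection


def small_cfg(**kw):
    base = dict(
        n_chrom=1,
        chrom_cm=100.0,
        chrom_bp=10_000_000,
        n_markers_per_chrom=500,
        n_qtl_per_chrom=2,
        qtl_positions_cm=(30.0, 70.0),
        n_sires=10,
        n_dams=10,
        litter_size=20,
        n_generations=10,
        burnin_popsize=100,
        burnin_generations=10,
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError, match="h2"):
        small_cfg(h2=0.0)
    with pytest.raises(ValueError, match="QTL positions"):
        small_cfg(qtl_positions_cm=(30.0, 150.0))
    with pytest.raises(ValueError, match="selection_mode"):
        small_cfg(selection_mode="stabilizing")


def test_genome_layout():
    g = build_genome(small_cfg(), np.random.default_rng(0))
    assert g.n_loci == 502
    assert g.is_qtl.sum() == 2
    # sorted within chromosome, QTL at the mapped bp positions
    assert np.all(np.diff(g.pos_bp) > 0)
    np.testing.assert_array_equal(g.pos_bp[g.is_qtl], [3_000_000, 7_000_000])
    assert g.bp_to_cm(5_000_000) == pytest.approx(50.0)


def test_replicate_determinism():
    a = simulate_replicate(small_cfg(), seed=7)
    b = simulate_replicate(small_cfg(), seed=7)
    pd.testing.assert_frame_equal(a.markers, b.markers)
    pd.testing.assert_frame_equal(a.qtl, b.qtl)
    c = simulate_replicate(small_cfg(), seed=8)
    assert not a.markers.equals(c.markers)


def test_frequencies_bounded_and_qtl_excluded_from_markers():
    rep = simulate_replicate(small_cfg(), seed=3)
    m = rep.markers
    assert ((m.FREQ_PRE >= 0) & (m.FREQ_PRE <= 1)).all()
    assert ((m.FREQ_POST >= 0) & (m.FREQ_POST <= 1)).all()
    assert not set(rep.qtl.POS) & set(m.POS)


def test_truncation_selection_raises_trait_mean():
    # response is monotone until the (few) QTL fix, then exactly flat
    for seed in (5, 6, 7):
        rep = simulate_replicate(small_cfg(), seed=seed)
        tm = np.array(rep.trait_means)
        gain = tm[-1] - tm[0]
        assert gain > 0
        assert np.all(np.diff(tm) >= -0.05 * gain)


def test_site_frequency_spectrum_symmetric():
    # no selection + symmetric mutation: founder frequencies have mean 1/2
    cfg = small_cfg(n_markers_per_chrom=3000)
    freqs = []
    for seed in (0, 1):
        pool = run_burnin(cfg, np.random.default_rng(seed))
        f = pool.haplotypes.mean(axis=(0, 1))
        freqs.append(f[(f > 0) & (f < 1)])
    f = np.concatenate(freqs)
    assert abs(np.mean(f) - 0.5) < 0.03
    assert abs(np.mean(f**3) - np.mean((1 - f) ** 3)) < 0.01


def test_ld_decays_with_genetic_distance():
    # drift during the burn-in builds r^2 at short range, none at 10 cM
    cfg = small_cfg(n_markers_per_chrom=400)
    near, far = [], []
    for seed in (0, 1, 2):
        pool = run_burnin(cfg, np.random.default_rng(seed))
        g = pool.genome
        hap = pool.haplotypes.reshape(-1, g.n_loci).astype(float)
        f = hap.mean(axis=0)
        poly = np.nonzero((f > 0.05) & (f < 0.95))[0]

        def r2(i, j):
            a, b = hap[:, i], hap[:, j]
            va, vb = a.var(), b.var()
            return ((a * b).mean() - a.mean() * b.mean()) ** 2 / (va * vb)

        cm = g.pos_cm
        for i, j in zip(poly[:-1], poly[1:]):
            if cm[j] - cm[i] < 0.5:
                near.append(r2(i, j))
        rngl = np.random.default_rng(seed)
        for i in rngl.choice(poly, 200):
            cand = poly[np.abs(cm[poly] - cm[i] - 10.0) < 0.5]
            if cand.size:
                far.append(r2(i, cand[0]))
    assert np.mean(near) > 2 * np.mean(far)


def test_null_drift_fst_matches_wright_fisher_prediction():
    """Mean FST between generation 0 and T under random selection.

    Oracle: F_t = 1 - (1 - 1/(2 Ne))^t with the two-sex effective size
    Ne = 4 Nm Nf' / (Nm + Nf'), Nf' = 2 Nf (litter sizes equalized) and
    Nm = n_sires (multinomial sire use).  The two-population estimator
    applied to (ancestral, drifted) frequencies has expectation ~ F_t / 2.
    The band covers the estimator's known positive ratio bias (~+20%).
    """
    cfg = small_cfg(selection_mode="random", n_markers_per_chrom=800)
    ne = 4 * 10 * 20 / (10 + 20)
    f_t = 1 - (1 - 1 / (2 * ne)) ** cfg.n_generations
    predicted = f_t / 2
    obs = []
    for seed in (100, 101, 102):
        rep = simulate_replicate(cfg, seed=seed)
        fst = fst_array(rep.markers.FREQ_PRE.to_numpy(), rep.markers.FREQ_POST.to_numpy())
        obs.append(np.nanmean(fst))
    ratio = np.mean(obs) / predicted
    assert 0.6 < ratio < 1.6


def test_null_fst_has_no_positional_trend():
    # drift peaks make any single replicate's slope nonzero; stationarity
    # means the slope is centered on zero across replicates
    slopes = []
    for seed in range(11, 19):
        rep = simulate_replicate(small_cfg(selection_mode="random"), seed=seed)
        fst = fst_array(rep.markers.FREQ_PRE.to_numpy(), rep.markers.FREQ_POST.to_numpy())
        ok = np.isfinite(fst)
        x = rep.markers.POS.to_numpy(float)[ok]
        slopes.append(np.polyfit((x - x.mean()) / x.std(), fst[ok], 1)[0])
    slopes = np.array(slopes)
    assert abs(slopes.mean()) <= 2.5 * slopes.std(ddof=1) / np.sqrt(slopes.size)


def test_hitchhiking_elevates_fst_near_qtl():
    """Paired comparison, near-QTL vs chromosome-wide mean FST.

    Hitchhiking needs marker-QTL LD (longer burn-in) and sweeps slow enough
    to drag it (polygenic trait, strong intensity); the tiny-census drift
    noise makes single replicates inconclusive, so the assertion is on the
    paired mean over 30 seeded replicates.
    """
    cfg = small_cfg(
        n_markers_per_chrom=400,
        litter_size=50,
        n_generations=20,
        burnin_generations=40,
    )
    diffs = []
    for seed in range(200, 230):
        rep = simulate_replicate(cfg, seed=seed)
        fst = fst_array(rep.markers.FREQ_PRE.to_numpy(), rep.markers.FREQ_POST.to_numpy())
        cm = rep.genome.bp_to_cm(rep.markers.POS.to_numpy())
        qcm = rep.genome.bp_to_cm(rep.qtl.POS.to_numpy())
        near = np.zeros(len(cm), bool)
        for q in qcm:
            near |= np.abs(cm - q) <= 5.0
        ok = np.isfinite(fst)
        diffs.append(np.nanmean(fst[near & ok]) - np.nanmean(fst[ok]))
    diffs = np.array(diffs)
    t_stat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
    assert diffs.mean() > 0
    assert t_stat > 1.0


def test_degenerate_trait_rejected():
    cfg = small_cfg()
    rng = np.random.default_rng(0)
    genome = build_genome(cfg, rng)
    haps = np.zeros((cfg.burnin_popsize, 2, genome.n_loci), dtype=np.uint8)
    founders = FounderPool(genome=genome, haplotypes=haps)
    with pytest.raises(ValueError, match="degenerate trait"):
        run_selection(cfg, founders, rng)


def test_pooled_dataset_deterministic_and_inflates_variance():
    rep = simulate_replicate(small_cfg(), seed=9)
    spec = PoolSpec()
    a = emit_pooled_dataset(rep, spec, rng=123)
    b = emit_pooled_dataset(rep, spec, rng=123)
    pd.testing.assert_frame_equal(a, b)
    raw = fst_array(rep.markers.FREQ_PRE.to_numpy(), rep.markers.FREQ_POST.to_numpy())
    noisy = fst_array(a.FREQ_PRE.to_numpy(), a.FREQ_POST.to_numpy())
    assert np.nanvar(noisy) > np.nanvar(raw)


def test_meiosis_respects_parental_alleles():
    # child alleles must be drawn from the parent's two haplotypes
    from splinewin.simulate import _meiosis

    cfg = small_cfg()
    rng = np.random.default_rng(4)
    genome = build_genome(cfg, rng)
    haps = np.zeros((2, 2, genome.n_loci), dtype=np.uint8)
    haps[0, 1] = 1  # parent 0: haplotypes all-0 and all-1
    gametes = _meiosis(haps, np.zeros(200, dtype=int), genome, rng)
    assert set(np.unique(gametes)) <= {0, 1}
    # parent 1 is fully homozygous 0: gametes must be all zero
    g2 = _meiosis(haps, np.ones(50, dtype=int), genome, rng)
    assert not g2.any()
    # crossover structure: allele switches along the chromosome are few
    switches = np.abs(np.diff(gametes.astype(int), axis=1)).sum(axis=1)
    assert switches.mean() < 6  # ~Poisson(1 Morgan) crossovers, not noise
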