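import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from staygreen import association as assoc
from staygreen import mixed_model as mm
from staygreen import synthetic_data as sd


def toy_genotypes(dosages, positions=None, chrom="1A", cultivars=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = [f"m{j}" for j in range(m)]
    if positions is None:
        positions = np.arange(m, dtype=float)
    mm_ = pd.DataFrame({"marker": markers, "chromosome": chrom, "position_mbp": positions})
    return sd.GenotypeMatrix(
        cultivars=cultivars or [f"c{i}" for i in range(n)],
        markers=markers,
        dosages=dosages,
        marker_map=mm_,
    )


def blues_for(cultivars, values, trait="t"):
    return pd.DataFrame(
        {"cultivar": cultivars, "trait": trait, "blue": values, "season": np.nan}
    )


@pytest.fixture(scope="module")
def scan_setup(structured_genotypes_module):
    panel, geno = structured_genotypes_module
    fit = mm.fit_mixed_model(panel, mm.ModelSpec.blue_model("gcd"))
    blues = mm.estimate_blues(fit)
    geno_qc, report = assoc.marker_qc(geno)
    K = assoc.kinship(geno_qc)
    structure = assoc.population_structure(geno_qc, k=5, seed=0)
    return panel, geno, blues, geno_qc, K, structure


@pytest.fixture(scope="module")
def structured_genotypes_module():
    cfg = sd.PanelConfig(
        n_cultivars=100,
        trait_means={"gcd": 330.0},
        trait_slopes={"gcd": 0.0},
        var_components={"gcd": (100.0, 0.0, 0.0, 0.0, 50.0)},
        seed=5,
    )
    panel = sd.simulate_panel(cfg)
    gcfg = sd.GenoSimConfig(
        n_markers=1200,
        n_groups=5,
        missing_rate=0.02,
        causal_region=("6A", 400.0, 442.0, -25.0),
        seed=5,
    )
    geno = sd.simulate_genotypes(gcfg, panel)
    panel = sd.apply_causal_effect(panel, geno, "gcd")
    return panel, geno


class TestMarkerQC:
    def test_monomorphic_dropped(self):
        d = np.zeros((20, 3))
        d[:, 1] = np.tile([0, 2], 10)
        d[:, 2] = np.tile([0, 2], 10)
        g = toy_genotypes(d)
        out, report = assoc.marker_qc(g)
        assert report.n_monomorphic == 1
        assert out.markers == ["m1", "m2"]

    def test_hand_enumerated_toy_matrix(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0.0, 2.0], size=(20, 10))
        d[:, 0] = 2.0                       # monomorphic -> drop
        d[:3, 1] = np.nan                   # 15% missing -> drop
        d[:, 2] = 0.0
        d[0, 2] = 2.0                       # MAF 0.05 -> keep (boundary)
        d[:, 3] = 0.0
        d[0, 3] = 1.0                       # MAF 1/40 = 0.025 < 0.05 -> drop
        d[:2, 4] = np.nan                   # 10% missing -> keep (boundary)
        g = toy_genotypes(d)
        out, report = assoc.marker_qc(g)
        surviving = set(out.markers)
        assert "m0" not in surviving
        assert "m1" not in surviving
        assert "m2" in surviving
        assert "m3" not in surviving
        assert "m4" in surviving

    def test_postconditions_hold(self, structured_genotypes_module):
        _, geno = structured_genotypes_module
        out, _ = assoc.marker_qc(geno, max_missing=0.10, min_maf=0.05)
        d = out.dosages
        miss = np.isnan(d).mean(axis=0)
        mafs = np.array([assoc._maf(d[:, j]) for j in range(d.shape[1])])
        assert miss.max() <= 0.10
        assert mafs.min() >= 0.05

    def test_empty_output_raises_with_counts(self):
        g = toy_genotypes(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="monomorphic"):
            assoc.marker_qc(g)


class TestKinship:
    def test_identical_lines_share_diagonal(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0.0, 2.0], size=(10, 300))
        d[1] = d[0]
        K = assoc.kinship(toy_genotypes(d))
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], rel=1e-12)

    def test_unrelated_lines_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 20000)
        d = 2.0 * (rng.random((30, 20000)) < p)
        K = assoc.kinship(toy_genotypes(d))
        off = K[~np.eye(30, dtype=bool)]
        # sample centering leaves a -diag/(n-1) artifact; remove it first
        centering = -K.diagonal().mean() / (30 - 1)
        assert np.abs(off - centering).mean() < 0.02

    def test_positive_semidefinite(self, structured_genotypes_module):
        _, geno = structured_genotypes_module
        K = assoc.kinship(geno)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert np.allclose(K, K.T)

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.choice([0.0, 2.0], size=(8, 50))
        g = toy_genotypes(d)
        perm = rng.permutation(50)
        g2 = g.subset_markers([g.markers[j] for j in perm])
        assert np.allclose(assoc.kinship(g), assoc.kinship(g2))

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError, match="2 markers"):
            assoc.kinship(toy_genotypes(np.zeros((5, 1))))


class TestPopulationStructure:
    def test_group_recovery(self, structured_genotypes_module):
        _, geno = structured_genotypes_module
        geno_qc, _ = assoc.marker_qc(geno)
        st_ = assoc.population_structure(geno_qc, k=5, seed=0)
        assert adjusted_rand_score(geno.groups, st_.groups) > 0.9

    def test_k1_degenerate(self, structured_genotypes_module):
        _, geno = structured_genotypes_module
        st_ = assoc.population_structure(geno, k=1)
        assert set(st_.groups) == {0}
        assert st_.indicators().shape == (geno.n_cultivars, 0)

    def test_order_invariance_up_to_labels(self, structured_genotypes_module):
        _, geno = structured_genotypes_module
        st1 = assoc.population_structure(geno, k=5, seed=0)
        rng = np.random.default_rng(9)
        perm = rng.permutation(geno.n_cultivars)
        g2 = sd.GenotypeMatrix(
            cultivars=[geno.cultivars[i] for i in perm],
            markers=list(geno.markers),
            dosages=geno.dosages[perm, :],
            marker_map=geno.marker_map,
        )
        st2 = assoc.population_structure(g2, k=5, seed=0)
        assert adjusted_rand_score(st1.groups[perm], st2.groups) == pytest.approx(1.0)

    def test_k_exceeding_n_rejected(self):
        g = toy_genotypes(np.tile([0.0, 2.0], (4, 5)))
        with pytest.raises(ValueError, match="exceeds"):
            assoc.population_structure(g, k=10)


class TestAssociationScan:
    def test_causal_markers_rank_first(self, scan_setup):
        panel, geno, blues, geno_qc, K, structure = scan_setup
        scan = assoc.association_scan(blues, geno_qc, K, structure, trait="gcd")
        top = scan.nsmallest(1, "p_value")["marker"].iloc[0]
        assert top in geno.causal_markers

    def test_explained_variance_close_to_planted(self, scan_setup):
        panel, geno, blues, geno_qc, K, structure = scan_setup
        scan = assoc.association_scan(blues, geno_qc, K, structure, trait="gcd")
        top = scan.nsmallest(1, "p_value").iloc[0]
        # independent oracle: squared correlation of the top causal dosage
        # with the cultivar BLUEs, in percent
        b = blues[blues["season"].isna()].set_index("cultivar")["blue"]
        j = geno_qc.markers.index(top["marker"])
        dos = geno_qc.dosages[:, j]
        ok = ~np.isnan(dos)
        cvs = [c for c, o in zip(geno_qc.cultivars, ok) if o]
        planted = 100.0 * np.corrcoef(dos[ok], b.loc[cvs])[0, 1] ** 2
        assert abs(top["explained_pct"] - planted) < 5.0

    def test_null_type_one_error(self):
        cfg = sd.PanelConfig(
            n_cultivars=80, trait_means={"t": 10.0}, trait_slopes={"t": 0.0},
            var_components={"t": (1.0, 0.0, 0.0, 0.0, 1.0)}, seed=21,
        )
        panel = sd.simulate_panel(cfg)
        geno = sd.simulate_genotypes(
            sd.GenoSimConfig(n_markers=3000, n_groups=1, seed=21), panel
        )
        blues = mm.estimate_blues(mm.fit_mixed_model(panel, mm.ModelSpec.blue_model("t")))
        geno_qc, _ = assoc.marker_qc(geno)
        K = assoc.kinship(geno_qc)
        scan = assoc.association_scan(blues, geno_qc, K, None, trait="t")
        p = scan["p_value"].dropna().to_numpy()
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < 5 * se + 0.01

    def test_permuted_phenotype_lambda_near_one(self, scan_setup):
        panel, geno, blues, geno_qc, K, structure = scan_setup
        b = blues.copy()
        sel = b["season"].isna()
        rng = np.random.default_rng(4)
        b.loc[sel, "blue"] = rng.permutation(b.loc[sel, "blue"].to_numpy())
        scan = assoc.association_scan(b, geno_qc, K, structure, trait="gcd")
        lam = assoc.genomic_control_lambda(scan["p_value"].dropna())
        assert abs(lam - 1.0) < 0.1

    def test_constant_phenotype_rejected(self, scan_setup):
        _, _, blues, geno_qc, K, structure = scan_setup
        b = blues.copy()
        b["blue"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            assoc.association_scan(b, geno_qc, K, structure, trait="gcd")

    def test_disjoint_ids_rejected(self, scan_setup):
        _, _, blues, geno_qc, K, structure = scan_setup
        b = blues.copy()
        b["cultivar"] = "zz_" + b["cultivar"]
        with pytest.raises(ValueError, match="overlap"):
            assoc.association_scan(b, geno_qc, K, structure, trait="gcd")

    def test_markers_with_missing_get_tested(self, scan_setup):
        _, _, blues, geno_qc, K, structure = scan_setup
        scan = assoc.association_scan(blues, geno_qc, K, structure, trait="gcd")
        has_missing = np.isnan(geno_qc.dosages).any(axis=0)
        assert scan.loc[has_missing, "p_value"].notna().mean() > 0.95


class TestSignificanceThresholds:
    def test_study_scale_bonferroni(self):
        th = assoc.significance_thresholds(45_370, alpha=0.05)
        assert round(th.bonferroni_neglog10, 2) == 5.96

    def test_single_marker(self):
        th = assoc.significance_thresholds(1, alpha=0.05)
        assert th.bonferroni_neglog10 == pytest.approx(1.301, abs=5e-4)

    def test_bh_hand_computation(self):
        th = assoc.significance_thresholds(
            4, fdr_rate=0.10, pvalues=[0.001, 0.01, 0.02, 0.5]
        )
        assert th.n_bh_rejected == 3
        assert th.bh_p_cutoff == pytest.approx(0.02)

    def test_bonferroni_increasing_in_n(self):
        cuts = [assoc.significance_thresholds(n).bonferroni_neglog10 for n in (10, 100, 1000)]
        assert cuts == sorted(cuts)
        assert cuts[0] < cuts[1] < cuts[2]

    def test_bh_rejections_monotone_in_rate(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(0, 0.01, 20), rng.uniform(0, 1, 400)])
        counts = [
            assoc.significance_thresholds(len(p), fdr_rate=q, pvalues=p).n_bh_rejected
            for q in (0.01, 0.05, 0.10, 0.25)
        ]
        assert counts == sorted(counts)

    def test_empty_pvalues_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assoc.significance_thresholds(10, pvalues=[])


class TestLdR2:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(5)
        d = rng.choice([0.0, 2.0], size=(30, 6))
        out = assoc.ld_r2(toy_genotypes(d)).to_numpy()
        valid = ~np.isnan(out)
        assert np.allclose(out[valid], out.T[valid])
        diag = np.diag(out)
        assert np.allclose(diag[~np.isnan(diag)], 1.0)
        assert np.nanmin(out) >= 0 and np.nanmax(out) <= 1 + 1e-12

    def test_perfect_coupling(self):
        col = np.tile([0.0, 2.0], 10)
        d = np.column_stack([col, col])
        out = assoc.ld_r2(toy_genotypes(d))
        assert out.iloc[0, 1] == pytest.approx(1.0)

    def test_haplotype_frequency_oracle(self):
        # 100 inbred lines from 4 haplotypes: AB x40, Ab x10, aB x10, ab x40
        hapA = np.array([1] * 40 + [1] * 10 + [0] * 10 + [0] * 40, dtype=float)
        hapB = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40, dtype=float)
        d = np.column_stack([2 * hapA, 2 * hapB])
        pA = pB = 0.5
        pAB = 0.40
        D = pAB - pA * pB
        expected = D**2 / (pA * (1 - pA) * pB * (1 - pB))
        out = assoc.ld_r2(toy_genotypes(d))
        assert out.iloc[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_monomorphic_marker_reported_missing(self):
        d = np.column_stack([np.tile([0.0, 2.0], 10), np.full(20, 2.0)])
        out = assoc.ld_r2(toy_genotypes(d))
        assert np.isnan(out.iloc[0, 1])

    def test_era_subset_means_differ(self, structured_genotypes_module):
        _, geno = structured_genotypes_module
        region = geno.marker_map[
            (geno.marker_map["chromosome"] == "6A")
            & geno.marker_map["position_mbp"].between(400, 442)
        ]["marker"].tolist()
        if len(region) >= 2:
            old = geno.cultivars[:40]
            new = geno.cultivars[60:]
            m_old = assoc.mean_ld(geno, region, old)
            m_new = assoc.mean_ld(geno, region, new)
            assert 0.0 <= m_old <= 1.0 and 0.0 <= m_new <= 1.0


class TestAlleleBurden:
    def test_single_marker_groups_equal_class_means(self):
        rng = np.random.default_rng(6)
        dos = np.tile([0.0, 2.0], 15)
        d = dos[:, None]
        g = toy_genotypes(d, positions=[5.0])
        y = 10.0 - 3.0 * (dos / 2.0) + rng.normal(0, 0.1, 30)
        blues = blues_for(g.cultivars, y)
        out = assoc.allele_burden(g, ("1A", 0.0, 10.0), blues, trait="t")
        tbl = out["group_summary"].set_index("burden")
        assert tbl.loc[0, "mean"] == pytest.approx(y[dos == 0].mean())
        assert tbl.loc[2, "mean"] == pytest.approx(y[dos == 2].mean())

    def test_additive_region_slope_recovered(self):
        rng = np.random.default_rng(7)
        n = 200
        d = 2.0 * (rng.random((n, 4)) < 0.4)
        g = toy_genotypes(d, positions=[1.0, 2.0, 3.0, 4.0])
        burden = d.sum(axis=1)
        y = 5.0 - 0.8 * burden + rng.normal(0, 0.3, n)
        out = assoc.allele_burden(g, ("1A", 0.0, 10.0), blues_for(g.cultivars, y), trait="t")
        assert out["slope_per_allele"] == pytest.approx(-0.8, abs=0.05)
        assert out["additive_lack_of_fit_p"] > 0.01  # no departure flagged

    def test_saturating_region_flags_non_additivity(self):
        rng = np.random.default_rng(8)
        n = 300
        d = 2.0 * (rng.random((n, 4)) < 0.4)
        g = toy_genotypes(d, positions=[1.0, 2.0, 3.0, 4.0])
        burden = d.sum(axis=1)
        y = np.where(burden >= 1, 2.0, 5.0) + rng.normal(0, 0.2, n)  # saturates at 1
        out = assoc.allele_burden(g, ("1A", 0.0, 10.0), blues_for(g.cultivars, y), trait="t")
        assert out["additive_lack_of_fit_p"] < 0.01
        tbl = out["group_summary"]
        beyond = tbl[tbl["burden"] >= 1]["mean"]
        assert beyond.max() - beyond.min() < 1.0  # flat beyond one allele

    def test_empty_region_rejected(self):
        g = toy_genotypes(np.tile([0.0, 2.0, 0.0], (10, 1)), positions=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="no markers"):
            assoc.allele_burden(g, ("1A", 100.0, 200.0), blues_for(g.cultivars, np.arange(10.0)), "t")
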