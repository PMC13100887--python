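"""Generators: landscapes, island/IBR/pedigree genotypes, VCF degradation."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from uhedge.genotype_io import MISSING, FilterConfig, apply_filter_chain
from uhedge.popgen import qg_relatedness, wc_fst
from uhedge.resistance import build_resistance_surface
from uhedge.synthetic_data import (
    ClassSpec,
    DepthModel,
    LandscapeSpec,
    PedigreeSpec,
    SyntheticError,
    SyntheticScenario,
    default_landscape_spec,
    degrade_to_vcf_records,
    generate_landscape,
    sample_locations,
    simulate_ibr_genotypes,
    simulate_island_genotypes,
    simulate_pedigree_genotypes,
    true_relationships,
)


class TestLandscape:
    def test_single_class_constant_raster(self):
        spec = LandscapeSpec(classes=[ClassSpec("Lawn", weight=1.0)])
        lc = generate_landscape(spec, seed=0)
        assert set(lc.legend[c] for c in np.unique(lc.codes)) == {"Lawn"}

    def test_vertical_road_strip_blocks_every_crossing(self):
        spec = LandscapeSpec(
            nrows=32, ncols=32,
            classes=[
                ClassSpec("Private Garden", weight=0.7),
                ClassSpec("Buildings", weight=0.3),
                ClassSpec("Large street", kind="linear", orientation="vertical", width=1),
            ],
        )
        lc = generate_landscape(spec, seed=3)
        road = lc.class_mask("Large street")
        # flood fill from the left edge over non-road cells must never reach
        # the right edge: the strip spans every row
        non_road = ~road
        labels, _ = ndimage.label(non_road, structure=np.ones((3, 3)))
        left = set(labels[:, 0][non_road[:, 0]])
        right = set(labels[:, -1][non_road[:, -1]])
        assert not (left & right)

    def test_deterministic_per_seed(self):
        spec = default_landscape_spec()
        a = generate_landscape(spec, seed=11)
        b = generate_landscape(spec, seed=11)
        assert np.array_equal(a.codes, b.codes)
        c = generate_landscape(spec, seed=12)
        assert not np.array_equal(a.codes, c.codes)

    def test_small_grid_rejected(self):
        with pytest.raises(SyntheticError, match="8x8"):
            generate_landscape(
                LandscapeSpec(nrows=4, ncols=4, classes=[ClassSpec("Lawn")]), 0
            )

    def test_empty_class_list_rejected(self):
        with pytest.raises(SyntheticError, match="empty"):
            generate_landscape(LandscapeSpec(classes=[]), 0)


class TestIslandModel:
    def test_zero_fst_gives_no_differentiation(self):
        gm, pops = simulate_island_genotypes(8, 20, 2000, 0.0, seed=1)
        theta = wc_fst(gm, pops).estimate
        assert abs(theta) < 0.01

    def test_theta_recovers_target(self):
        gm, pops = simulate_island_genotypes(8, 20, 2000, 0.10, seed=2)
        assert wc_fst(gm, pops).estimate == pytest.approx(0.10, abs=0.02)

    def test_single_locus_shape(self):
        gm, _ = simulate_island_genotypes(2, 3, 1, 0.1, seed=0)
        assert gm.n_loci == 1 and gm.n_samples == 6

    def test_deterministic(self):
        a, _ = simulate_island_genotypes(3, 5, 50, 0.1, seed=9)
        b, _ = simulate_island_genotypes(3, 5, 50, 0.1, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_invalid_fst_rejected(self):
        with pytest.raises(SyntheticError):
            simulate_island_genotypes(2, 2, 10, 1.0, seed=0)


@pytest.fixture(scope="module")
def setup(hypotheses):
    lc = generate_landscape(default_landscape_spec(), seed=5)
    surface = build_resistance_surface(lc, hypotheses["EMP"])
    locs = sample_locations(surface, 8, seed=6)
    return surface, locs


class TestIbrModel:

    def test_positive_distance_correlation_over_seeds(self, setup, hypotheses):
        from uhedge.connectivity import build_transition_graph, commute_distance
        from uhedge.popgen import genetic_distance

        surface, locs = setup
        cd = commute_distance(
            build_transition_graph(surface, epsilon=1e-4), locs
        ).values
        iu = np.triu_indices(len(locs), 1)
        hits = 0
        for seed in range(10):
            gm, meta = simulate_ibr_genotypes(
                surface=surface, locations=locs, n_loci=800, sigma2=1.0,
                seed=seed, n_per_location=1,
            )
            gd = genetic_distance(gm).values
            hits += np.corrcoef(gd[iu], np.log(cd[iu]))[0, 1] > 0
        assert hits == 10

    def test_tercile_ordering_each_seed(self, setup):
        from uhedge.connectivity import build_transition_graph, commute_distance
        from uhedge.popgen import genetic_distance

        surface, locs = setup
        cd = commute_distance(
            build_transition_graph(surface, epsilon=1e-4), locs
        ).values
        iu = np.triu_indices(len(locs), 1)
        d = cd[iu]
        q = np.quantile(d, [1 / 3, 2 / 3])
        for seed in range(10):
            gm, _ = simulate_ibr_genotypes(
                surface=surface, locations=locs, n_loci=800, sigma2=1.0,
                seed=seed, n_per_location=1,
            )
            g = genetic_distance(gm).values[iu]
            assert g[d <= q[0]].mean() < g[d >= q[1]].mean()

    def test_sigma_zero_is_panmixia(self, setup):
        from uhedge.connectivity import build_transition_graph, commute_distance
        from uhedge.popgen import genetic_distance

        surface, locs = setup
        gm, meta = simulate_ibr_genotypes(
            surface=surface, locations=locs, n_loci=1500, sigma2=0.0,
            seed=3, n_per_location=3,
        )
        gd = genetic_distance(gm).values
        cd = commute_distance(
            build_transition_graph(surface, epsilon=1e-4),
            meta[["id", "x", "y"]],
        ).values
        iu = np.triu_indices(gm.n_samples, 1)
        assert abs(np.corrcoef(gd[iu], cd[iu])[0, 1]) < 0.1

    def test_deterministic(self, setup):
        surface, locs = setup
        a, _ = simulate_ibr_genotypes(locs, surface, 100, sigma2=1.0, seed=4)
        b, _ = simulate_ibr_genotypes(locs, surface, 100, sigma2=1.0, seed=4)
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_location_on_barrier_rejected(self, setup, hypotheses):
        surface, _ = setup
        rr, cc = np.nonzero(surface.barrier)
        x, y = surface.cell_center(rr[0], cc[0])
        bad = pd.DataFrame({"id": ["b"], "x": [x], "y": [y]})
        with pytest.raises(SyntheticError, match="barrier"):
            simulate_ibr_genotypes(bad, surface, 10, sigma2=1.0, seed=0)

    def test_nonpositive_phi_rejected(self, setup):
        surface, locs = setup
        with pytest.raises(SyntheticError, match="phi"):
            simulate_ibr_genotypes(locs, surface, 10, phi=-1.0, sigma2=1.0, seed=0)


def big_pedigree(n_founders=40, n_fam=8):
    entries = [(f"F{i}", None, None) for i in range(1, n_founders + 1)]
    for k in range(1, n_fam + 1):
        dam, sire = f"F{2 * k - 1}", f"F{2 * k}"
        entries += [
            (f"O{k}a", dam, sire),
            (f"O{k}b", dam, sire),
            (f"H{k}", dam, f"F{2 * k + 20}"),
        ]
    return PedigreeSpec(entries=entries, clones=[("C1", "F31")])


class TestPedigree:
    def test_relationship_class_means(self):
        gm, rel = simulate_pedigree_genotypes(big_pedigree(), 1000, seed=1)
        r = qg_relatedness(gm)
        means = {
            lab: np.mean(
                [r.loc[a, b] for a, b in zip(sub["id_a"], sub["id_b"])]
            )
            for lab, sub in rel.groupby("relationship")
            if lab in {"clone", "parent_offspring", "full_sib", "half_sib", "unrelated"}
        }
        assert means["clone"] == pytest.approx(1.0, abs=0.05)
        assert means["parent_offspring"] == pytest.approx(0.5, abs=0.05)
        assert means["full_sib"] == pytest.approx(0.5, abs=0.05)
        assert means["half_sib"] == pytest.approx(0.25, abs=0.05)
        assert means["unrelated"] == pytest.approx(0.0, abs=0.05)
        # class ordering: clone > PO ~ FS > HS > unrelated
        assert means["clone"] > means["parent_offspring"] > means["half_sib"] > means["unrelated"]

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(SyntheticError, match="not defined earlier"):
            PedigreeSpec(entries=[("A", "B", "C"), ("B", None, None), ("C", None, None)])

    def test_founder_frequency_bounds(self):
        with pytest.raises(SyntheticError, match="\\(0, 1\\)"):
            simulate_pedigree_genotypes(
                PedigreeSpec(entries=[("A", None, None)],
                             founder_freqs=np.array([0.0, 0.5])),
                2, seed=0,
            )

    def test_relationship_labels(self):
        ped = PedigreeSpec(
            entries=[("F1", None, None), ("F2", None, None), ("F3", None, None),
                     ("O1", "F1", "F2"), ("O2", "F1", "F3")],
            clones=[("K", "F1")],
        )
        rel = true_relationships(ped).set_index(["id_a", "id_b"])["relationship"]
        assert rel[("F1", "O1")] == "parent_offspring"
        assert rel[("F1", "F2")] == "unrelated"
        assert rel[("O1", "O2")] == "half_sib"
        assert rel[("F1", "K")] == "clone"


class TestDegradeToVcf:
    def test_generous_model_passes_all_filters(self):
        gm, _ = simulate_island_genotypes(2, 10, 40, 0.3, seed=8)
        samples, recs = degrade_to_vcf_records(
            gm, missing_rate=0.0, depth_model=DepthModel(mean_depth=40), seed=1
        )
        out, report = apply_filter_chain(samples, recs,
                                         FilterConfig(min_mac=0))
        assert out.n_loci == gm.n_loci

    def test_forced_low_mean_depth_removed(self):
        gm, _ = simulate_island_genotypes(2, 5, 3, 0.1, seed=0)
        samples, recs = degrade_to_vcf_records(gm, seed=1)
        recs[1].depths[:] = 9
        out, report = apply_filter_chain(samples, recs, FilterConfig(min_mac=0))
        assert out.n_loci == 2
        assert dict(zip([s[0] for s in report.steps],
                        [s[2] for s in report.steps]))["mean_depth"] == 2

    def test_high_missing_individual_exceeds_cut(self):
        from uhedge.genotype_io import remove_high_missing_individuals

        gm, _ = simulate_island_genotypes(2, 5, 400, 0.1, seed=0)
        rates = np.zeros(gm.n_samples)
        rates[0] = 0.3
        samples, recs = degrade_to_vcf_records(gm, missing_rate=rates, seed=2)
        out, _ = apply_filter_chain(
            samples, recs, FilterConfig(min_mac=0, max_site_missing=1.0)
        )
        out, removed = remove_high_missing_individuals(out, 0.20)
        assert removed == [gm.samples[0]]

    def test_valid_vcf_output(self, tmp_path):
        from uhedge.genotype_io import read_vcf, write_vcf

        gm, _ = simulate_island_genotypes(2, 3, 5, 0.1, seed=0)
        samples, recs = degrade_to_vcf_records(gm, missing_rate=0.1, seed=1)
        write_vcf(samples, recs, tmp_path / "d.vcf")
        back_samples, back = read_vcf(tmp_path / "d.vcf")
        assert back_samples == samples and len(back) == 5


class TestScenario:
    def test_yaml_round_trip(self, tmp_path):
        (tmp_path / "s.yaml").write_text(
            "seed: 3\nn_pops: 4\nn_loci: 100\nfst_target: 0.2\n"
            "landscape:\n  nrows: 16\n  ncols: 16\n  resolution: 5.0\n"
            "  classes:\n    - name: Lawn\n      weight: 1.0\n"
        )
        sc = SyntheticScenario.from_yaml(tmp_path / "s.yaml")
        assert sc.n_pops == 4 and sc.landscape.nrows == 16
        assert sc.landscape.classes[0].name == "Lawn"

    def test_invalid_rates_rejected(self):
        with pytest.raises(SyntheticError):
            SyntheticScenario(missing_rate=1.5)
        with pytest.raises(SyntheticError):
            SyntheticScenario(fst_target=1.0)
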