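"""Relative abundances, spike-normalised concentrations, charcoal, folds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fernspike import assemblage as asm


def make_sample(counts, depth=80.0, lyco_counted=50, lyco_spiked=20000,
                dry_weight=2.0, palynofacies=None, tephra=False):
    return asm.PalynoSample(
        depth_mbsf=depth,
        taxon_counts=counts,
        lyco_counted=lyco_counted,
        lyco_spiked=lyco_spiked,
        dry_weight_g=dry_weight,
        palynofacies_counts=palynofacies or {},
        tephra_flag=tephra,
    )


class TestRelativeAbundance:
    def test_single_group_is_100pct(self, groups):
        s = make_sample({"Gleicheniaceae": 37})
        assert asm.relative_abundance(s, groups)["fern"] == 100.0

    def test_marine_and_marker_excluded(self, groups):
        # 40 fern + 60 other terrestrial, with marine grains on the slide:
        # fern is 40 % of the *terrestrial* assemblage.
        s = make_sample(
            {"Gleicheniaceae": 40, "other_terrestrial_palynomorphs": 60,
             "dinocysts": 20},
            lyco_counted=500,
        )
        pct = asm.relative_abundance(s, groups)
        assert pct["fern"] == pytest.approx(40.0)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_matches_hand_summation(self, groups):
        rng = np.random.default_rng(11)
        taxa = list(groups.taxon_to_group)
        for _ in range(20):
            counts = {t: int(rng.integers(0, 80)) for t in taxa if t != "Lycopodium_marker"}
            s = make_sample(counts)
            terr = {
                t: c for t, c in counts.items()
                if groups.is_terrestrial(groups.group_of(t))
            }
            if sum(terr.values()) == 0:
                continue
            pct = asm.relative_abundance(s, groups)
            # independent brute-force oracle
            for g in groups.terrestrial_groups:
                expected = 100.0 * sum(
                    c for t, c in terr.items() if groups.group_of(t) == g
                ) / sum(terr.values())
                assert pct[g] == pytest.approx(expected)

    def test_percents_sum_to_100(self, noisy_record, groups):
        for s in noisy_record.samples:
            if s.tephra_flag:
                continue
            pct = asm.relative_abundance(s, groups)
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_terrestrial_raises_with_depth(self, groups):
        s = make_sample({"dinocysts": 10}, depth=80.44)
        with pytest.raises(asm.UndefinedQuantityError, match="80.44"):
            asm.relative_abundance(s, groups)

    @given(k=st.integers(min_value=2, max_value=50))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, k):
        groups = asm.default_group_map()
        base = {"Gleicheniaceae": 12, "Alnipollenites": 5, "Pinaceae_pollen": 33}
        s1 = make_sample(base)
        s2 = make_sample({t: k * c for t, c in base.items()})
        p1, p2 = (asm.relative_abundance(s, groups) for s in (s1, s2))
        for g in p1:
            assert p1[g] == pytest.approx(p2[g])


class TestConcentration:
    def test_direct_arithmetic(self, groups):
        s = make_sample({"Gleicheniaceae": 50}, lyco_counted=50,
                        lyco_spiked=20000, dry_weight=2.0)
        assert asm.concentration(s, "Gleicheniaceae") == pytest.approx(10000.0)

    def test_zero_count_gives_zero(self, groups):
        s = make_sample({"Gleicheniaceae": 0, "Pinaceae_pollen": 10})
        assert asm.concentration(s, "Gleicheniaceae") == 0.0

    def test_no_marker_counted_raises(self, groups):
        s = make_sample({"Gleicheniaceae": 5}, lyco_counted=0)
        with pytest.raises(asm.UndefinedQuantityError):
            asm.concentration(s, "Gleicheniaceae")

    @given(
        count=st.integers(min_value=1, max_value=500),
        lyco=st.integers(min_value=1, max_value=200),
        spiked=st.integers(min_value=1000, max_value=50000),
        weight=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_homogeneity(self, count, lyco, spiked, weight):
        """conc is degree-1 in count and spiked, degree -1 in marker count
        and dry weight."""
        def conc(c, l, sp, w):
            return asm.concentration(
                make_sample({"Gleicheniaceae": c}, lyco_counted=l,
                            lyco_spiked=sp, dry_weight=w),
                "Gleicheniaceae",
            )

        base = conc(count, lyco, spiked, weight)
        assert conc(2 * count, lyco, spiked, weight) == pytest.approx(2 * base)
        assert conc(count, lyco, 2 * spiked, weight) == pytest.approx(2 * base)
        assert conc(count, 2 * lyco, spiked, weight) == pytest.approx(base / 2)
        assert conc(count, lyco, spiked, 2 * weight) == pytest.approx(base / 2)

    def test_group_selector_sums_taxa(self, groups):
        s = make_sample({"Gleicheniaceae": 30, "other_fern_spores": 10})
        assert asm.concentration(s, "fern", groups) == pytest.approx(
            asm.concentration(s, "Gleicheniaceae")
            + asm.concentration(s, "other_fern_spores")
        )

    def test_unknown_selector_raises(self, groups):
        s = make_sample({"Gleicheniaceae": 5})
        with pytest.raises(KeyError):
            asm.concentration(s, "nope", groups)


class TestMicrocharcoal:
    def test_printed_fraction(self):
        s = make_sample({}, palynofacies={"microcharcoal": 13, "phytoclasts": 487})
        cf = asm.microcharcoal_fraction(s)
        assert cf.percent == pytest.approx(2.6)
        assert not cf.absent

    def test_absent_flag(self):
        s = make_sample({}, palynofacies={"microcharcoal": 0, "phytoclasts": 500})
        cf = asm.microcharcoal_fraction(s)
        assert cf.percent == 0.0
        assert cf.absent

    def test_empty_table_raises(self):
        with pytest.raises(asm.UndefinedQuantityError):
            asm.microcharcoal_fraction(make_sample({}))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            table = {f"cat{i}": int(rng.integers(0, 200)) for i in range(4)}
            table["microcharcoal"] = int(rng.integers(0, 50))
            if sum(table.values()) == 0:
                continue
            cf = asm.microcharcoal_fraction(make_sample({}, palynofacies=table))
            assert cf.percent == pytest.approx(
                100.0 * table["microcharcoal"] / sum(table.values())
            )


class TestFoldChange:
    def _record(self, pre_fern, post_fern):
        # pre samples deeper (81 m), post samples shallower (79 m); counts
        # chosen so concentrations equal the requested grains/g exactly.
        def sample(depth, fern_conc):
            count = int(round(fern_conc * 50 * 2.0 / 20000))
            return make_sample({"Gleicheniaceae": count}, depth=depth)

        return [sample(79.0, post_fern), sample(79.1, post_fern),
                sample(81.0, pre_fern), sample(81.1, pre_fern)]

    def test_identity(self, groups):
        samples = self._record(800, 56000)
        assert asm.fold_change(
            samples, "fern", (80.5, 81.5), (80.5, 81.5), groups
        ) == pytest.approx(1.0)

    def test_seventy_fold(self, groups):
        """Pre-event mean 800 grains/g rising to 56,000 grains/g: 70-fold."""
        samples = self._record(800, 56000)
        fc = asm.fold_change(samples, "fern", (80.5, 81.5), (78.5, 79.5), groups)
        assert fc == pytest.approx(70.0)

    def test_matches_independent_loop(self, noisy_record, groups):
        pre_iv, post_iv = (80.3, 81.0), (79.4, 80.2)
        fc = asm.fold_change(noisy_record, "fern", pre_iv, post_iv, groups)
        means = []
        for lo, hi in (pre_iv, post_iv):
            vals = []
            for s in noisy_record.samples:
                if lo <= s.depth_mbsf <= hi and not s.tephra_flag:
                    vals.append(asm.concentration(s, "fern", groups))
            means.append(sum(vals) / len(vals))
        assert fc == pytest.approx(means[1] / means[0])

    def test_zero_pre_mean_raises(self, groups):
        samples = self._record(0, 56000)
        with pytest.raises(asm.UndefinedQuantityError):
            asm.fold_change(samples, "fern", (80.5, 81.5), (78.5, 79.5), groups)

    def test_empty_interval_raises(self, groups):
        samples = self._record(800, 56000)
        with pytest.raises(asm.UndefinedQuantityError):
            asm.fold_change(samples, "fern", (90.0, 91.0), (78.5, 79.5), groups)


class TestIO:
    def test_counts_csv_round_trip(self, noisy_record, tmp_path):
        counts = tmp_path / "counts.csv"
        pf = tmp_path / "palynofacies.csv"
        asm.write_counts_csv(noisy_record.samples, counts, pf)
        back = asm.read_counts_csv(counts, pf)
        assert len(back) == len(noisy_record.samples)
        for a, b in zip(noisy_record.samples, back):
            assert a.depth_mbsf == b.depth_mbsf
            assert a.taxon_counts == b.taxon_counts
            assert a.palynofacies_counts == b.palynofacies_counts
            assert a.tephra_flag == b.tephra_flag

    def test_group_map_yaml_round_trip(self, groups, tmp_path):
        path = tmp_path / "groups.yaml"
        groups.to_yaml(path)
        back = asm.TaxonGroupMap.from_yaml(path)
        assert back == groups

    def test_round_sig(self):
        assert asm.round_sig(123456.0) == 123500.0
        assert asm.round_sig(0.0123456) == pytest.approx(0.01235)
        assert asm.round_sig(0.0) == 0.0

    def test_validation_rejects_bad_samples(self):
        with pytest.raises(ValueError):
            make_sample({"Gleicheniaceae": -1})
        with pytest.raises(ValueError):
            make_sample({"Gleicheniaceae": 1}, dry_weight=0.0)
        with pytest.raises(ValueError):
            make_sample({"": 1})
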