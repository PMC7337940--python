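"""Unit tests for the trans-mRNA background, normalization, enrichment."""

import numpy as np
import pandas as pd
import pytest

from redc.background import (
    BackgroundTrack,
    build_background,
    chromatin_type_enrichment,
    contact_frequency,
    fold_enrichment_profile,
    normalize_contacts,
)
from redc.genes import gene_frame
from redc.tracks import ChromatinStateTrack


def _genes():
    return gene_frame([
        {"gene_id": "pc1", "name": "PC1", "biotype": "protein_coding",
         "chrom": "chr1", "strand": "+", "start": 1000, "end": 2000,
         "exons": [(1000, 2000)]},
        {"gene_id": "nc1", "name": "NC1", "biotype": "lincRNA",
         "chrom": "chr1", "strand": "+", "start": 5000, "end": 6000,
         "exons": [(5000, 6000)]},
    ])


def _contacts(gene_ids, chroms, anchors):
    return pd.DataFrame({
        "gene_id": gene_ids, "dna_chrom": chroms,
        "dna_start": np.asarray(anchors), "dna_end": np.asarray(anchors) + 1,
        "weight": 1.0,
    })


SIZES = {"chr1": 100_000, "chr2": 100_000}


class TestBackgroundTrack:
    def test_zero_trans_contacts_give_empty_track(self):
        contacts = _contacts(["pc1"] * 5, ["chr1"] * 5, [10_000] * 5)  # all cis
        bg = build_background(contacts, _genes(), SIZES)
        assert all(v.sum() == 0 for v in bg.values.values())

    def test_noncoding_contacts_do_not_enter_background(self, rng):
        trans = _contacts(["pc1"] * 100, ["chr2"] * 100,
                          rng.integers(0, 100_000, 100))
        nc = _contacts(["nc1"] * 50, ["chr2"] * 50, rng.integers(0, 100_000, 50))
        bg1 = build_background(trans, _genes(), SIZES)
        bg2 = build_background(pd.concat([trans, nc], ignore_index=True), _genes(), SIZES)
        for c in SIZES:
            np.testing.assert_array_equal(bg1.values[c], bg2.values[c])

    def test_spike_smoothing_matches_explicit_convolution(self):
        contacts = _contacts(["pc1"], ["chr2"], [50_250])  # bin 100 at 500 bp
        sigma = 10.0
        bg = build_background(contacts, _genes(), SIZES, bin_size=500, sigma=sigma)
        vec = bg.values["chr2"]
        assert abs(vec.sum() - 1.0) < 1e-9
        # independent oracle: normalized discrete Gaussian kernel centred
        # on the spike bin (spike far from edges, so truncation is moot)
        k = np.arange(-40, 41)
        kernel = np.exp(-k**2 / (2 * sigma**2))
        kernel /= kernel.sum()
        expected = np.zeros_like(vec)
        expected[100 + k] = kernel
        np.testing.assert_allclose(vec, expected, atol=1e-6)

    def test_mass_preserved_under_smoothing(self, rng):
        n = 500
        contacts = _contacts(["pc1"] * n, ["chr2"] * n, rng.integers(0, 100_000, n))
        bg = build_background(contacts, _genes(), SIZES, sigma=25.0)
        assert abs(bg.values["chr2"].sum() - n) / n < 1e-9


class TestNormalization:
    def test_constant_background_gives_unit_weights(self):
        bg = BackgroundTrack(500, {"chr1": np.full(200, 3.7)}, sigma=0)
        contacts = _contacts([None] * 50, ["chr1"] * 50, np.arange(50) * 1000)
        out = normalize_contacts(contacts, bg)
        np.testing.assert_allclose(out["weight"], 1.0, atol=1e-12)

    def test_sum_of_weights_equals_raw_count(self, rng):
        vals = rng.random(200) * 5
        bg = BackgroundTrack(500, {"chr1": vals}, sigma=0)
        contacts = _contacts([None] * 300, ["chr1"] * 300,
                             rng.integers(0, 100_000, 300))
        out = normalize_contacts(contacts, bg)
        assert abs(out["weight"].sum() - 300) / 300 <= 1e-9

    def test_zero_background_bin_gets_finite_weight(self):
        vals = np.ones(200)
        vals[10] = 0.0
        bg = BackgroundTrack(500, {"chr1": vals}, sigma=0)
        contacts = _contacts([None, None], ["chr1", "chr1"], [5_250, 50_000])
        out = normalize_contacts(contacts, bg)
        assert np.isfinite(out["weight"]).all()
        assert out.loc[0, "weight"] > out.loc[1, "weight"]

    def test_all_zero_background_is_an_error(self):
        bg = BackgroundTrack(500, {"chr1": np.zeros(200)}, sigma=0)
        with pytest.raises(ValueError):
            normalize_contacts(_contacts([None], ["chr1"], [100]), bg)


class TestContactFrequency:
    @pytest.fixture()
    def states(self):
        return ChromatinStateTrack.from_frame(pd.DataFrame({
            "chrom": "chr1",
            "start": [0, 5000, 10_000],
            "end": [5000, 10_000, 20_000],
            "state": [1, 14, 12],
        }))

    def test_plain_frequency(self):
        anchors = pd.DataFrame({"chrom": ["chr1"] * 10,
                                "anchor": np.arange(10) * 400, "weight": 1.0})
        f = contact_frequency(anchors, ("chr1", 0, 5000))
        assert f == pytest.approx(10 / 5000)

    def test_masked_region_halves_denominator(self, states):
        anchors = pd.DataFrame({"chrom": ["chr1"] * 10,
                                "anchor": np.arange(10) * 400, "weight": 1.0})
        # region [0, 10000): half is state 14, so only 5000 bp count
        f = contact_frequency(anchors, ("chr1", 0, 10_000), states)
        assert f == pytest.approx(10 / 5000)

    def test_uniform_anchors_give_unit_type_enrichment(self, states, rng):
        pos = rng.integers(0, 20_000, 4000)
        anchors = pd.DataFrame({"chrom": "chr1", "anchor": pos, "weight": 1.0})
        e = chromatin_type_enrichment(anchors, {1, 12}, ("chr1", 0, 20_000), states)
        assert e == pytest.approx(1.0, rel=0.05)

    def test_concentrated_weight_scales_inversely_with_type_share(self, states):
        # all weight inside state-12 intervals occupying 10 of the 15
        # analysable kb: enrichment = 1 / share = 1.5
        anchors = pd.DataFrame({"chrom": "chr1",
                                "anchor": np.linspace(10_000, 19_999, 50, dtype=int),
                                "weight": 1.0})
        e = chromatin_type_enrichment(anchors, {12}, ("chr1", 0, 20_000), states)
        assert e == pytest.approx(1.5)

    def test_absent_type_is_an_error(self, states):
        anchors = pd.DataFrame({"chrom": ["chr1"], "anchor": [100], "weight": [1.0]})
        with pytest.raises(ValueError):
            contact_frequency(anchors, ("chr1", 0, 20_000), states, type_filter={5})

    def test_zero_effective_length_is_an_error(self, states):
        anchors = pd.DataFrame({"chrom": ["chr1"], "anchor": [100], "weight": [1.0]})
        with pytest.raises(ValueError):
            contact_frequency(anchors, ("chr1", 5000, 10_000), states)


class TestEnrichmentProfile:
    def test_background_identical_rna_yields_empty_profile(self, rng):
        from redc.scenarios import enrichment_library
        bg, genes, sizes, rnas, _ = enrichment_library(
            seed=11, n_background=30_000, n_rna=4000)
        prof = fold_enrichment_profile(rnas["rna_flat"], bg, genes, sizes)
        assert sum(r.sum() for r in prof.retained.values()) == 0

    def test_isolated_spike_removed_by_support_rule(self):
        from redc.scenarios import enrichment_library
        bg, genes, sizes, rnas, _ = enrichment_library(
            seed=12, n_background=30_000, n_rna=4000)
        prof = fold_enrichment_profile(rnas["rna_spike"], bg, genes, sizes)
        assert sum(r.sum() for r in prof.retained.values()) == 0

    def test_rna_with_no_contacts_gives_empty_profile(self):
        from redc.scenarios import enrichment_library
        bg, genes, sizes, _, _ = enrichment_library(
            seed=13, n_background=5000, n_rna=10)
        empty = pd.DataFrame(columns=["chrom", "anchor", "weight"])
        prof = fold_enrichment_profile(empty, bg, genes, sizes)
        assert prof.fold == {}
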