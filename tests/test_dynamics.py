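"""Unit tests for mRNA dynamics: part classes, metagene, asymmetry, scaling."""

import numpy as np
import pandas as pd
import pytest

from redc.dynamics import (
    classify_contacts,
    classify_part,
    cis_trans_summary,
    contacts_per_nt,
    directional_asymmetry,
    metagene_profile,
    scaling_curve,
)
from redc.genes import gene_frame
from redc.scenarios import _full_contact_row, metagene_library


@pytest.fixture(scope="module")
def three_exon_gene():
    # + strand: exon1 0-1000, intron1 1000-3000, exon2 3000-4000,
    # intron2 4000-6000, exon3 6000-7000
    return gene_frame([{
        "gene_id": "g", "name": "G", "biotype": "protein_coding",
        "chrom": "chr1", "strand": "+", "start": 0, "end": 7000,
        "exons": [(0, 1000), (3000, 4000), (6000, 7000)],
    }]).iloc[0]


class TestClassifyPart:
    def test_both_ends_same_exon(self, three_exon_gene):
        out = classify_part(100, 300, 1, three_exon_gene)
        assert (out.part_class, out.element_index) == ("exon", 1)

    def test_both_ends_same_intron(self, three_exon_gene):
        out = classify_part(1200, 1600, 1, three_exon_gene)
        assert (out.part_class, out.element_index) == ("intron", 1)

    def test_exon_into_next_intron(self, three_exon_gene):
        out = classify_part(3800, 4200, 1, three_exon_gene)
        assert out.part_class == "exon_intron"

    def test_intron_into_next_exon(self, three_exon_gene):
        out = classify_part(2800, 3200, 1, three_exon_gene)
        assert out.part_class == "exon_intron"

    def test_consecutive_exons_with_junction(self, three_exon_gene):
        out = classify_part(800, 3200, 2, three_exon_gene)
        assert out.part_class == "exon_exon"

    def test_consecutive_exons_without_junction_unclassified(self, three_exon_gene):
        assert classify_part(800, 3200, 1, three_exon_gene).part_class is None

    def test_ends_outside_gene_unclassified(self, three_exon_gene):
        assert classify_part(100, 9000, 1, three_exon_gene).part_class is None

    def test_gene_body_bin_orientation(self, three_exon_gene):
        assert classify_part(100, 200, 1, three_exon_gene).gene_body_bin == 1
        minus = dict(three_exon_gene)
        minus["strand"] = "-"
        assert classify_part(200, 100, 1, minus).gene_body_bin == 12

    def test_classes_mutually_exclusive_and_deterministic(self, three_exon_gene, rng):
        for _ in range(200):
            e5, e3 = sorted(rng.integers(0, 7000, size=2))
            a = classify_part(int(e5), int(e3), 1, three_exon_gene)
            b = classify_part(int(e5), int(e3), 1, three_exon_gene)
            assert a.part_class == b.part_class
            assert a.part_class in (None, "exon", "intron", "exon_intron")


class TestMetagene:
    def test_uniform_gene_body_contacts(self):
        genes = gene_frame([{
            "gene_id": "u", "name": "U", "biotype": "protein_coding",
            "chrom": "chr1", "strand": "+", "start": 12_000, "end": 24_000,
            "exons": [(12_000, 24_000)],
        }])
        rows = [_full_contact_row(f"r{i}", "chr1", "+", 12_100, 12_119,
                                  "chr1", anchor)
                for i, anchor in enumerate(range(12_000, 24_000, 10))]
        contacts = pd.DataFrame(rows)
        classified = classify_contacts(
            contacts, pd.Series(["u"] * len(contacts)), genes)
        profile = metagene_profile(contacts, classified, genes)
        assert profile[:6].sum() == 0 and profile[18:].sum() == 0
        assert np.all(profile[6:18] > 0.95)

    def test_strand_mirror_symmetry(self):
        genes = gene_frame([
            {"gene_id": "p", "name": "P", "biotype": "protein_coding",
             "chrom": "chr1", "strand": "+", "start": 100_000, "end": 112_000,
             "exons": [(100_000, 112_000)]},
            {"gene_id": "m", "name": "M", "biotype": "protein_coding",
             "chrom": "chr1", "strand": "-", "start": 300_000, "end": 312_000,
             "exons": [(300_000, 312_000)]},
        ])
        rng = np.random.default_rng(0)
        offsets = rng.integers(-6000, 18_000, size=400)  # relative to TSS
        rows, assign = [], []
        for i, off in enumerate(offsets):
            rows.append(_full_contact_row(f"p{i}", "chr1", "+", 100_050, 100_069,
                                          "chr1", 100_000 + off))
            assign.append("p")
            # mirrored contact for the minus-strand twin
            rows.append(_full_contact_row(f"m{i}", "chr1", "-", 311_950, 311_931,
                                          "chr1", 312_000 - off - 1))
            assign.append("m")
        contacts = pd.DataFrame(rows)
        classified = classify_contacts(contacts, pd.Series(assign), genes)
        plus = metagene_profile(contacts, classified.loc[classified.index % 2 == 0], genes)
        minus = metagene_profile(contacts, classified.loc[classified.index % 2 == 1], genes)
        np.testing.assert_allclose(plus, minus, atol=1e-12)


class TestAsymmetry:
    def test_symmetric_contacts_give_unit_ratios(self, rng):
        rows = []
        for i in range(4000):
            d = int(rng.integers(1, 400_000))
            sign = -1 if i % 2 else 1
            rows.append(_full_contact_row(f"s{i}", "chr1", "+", 5_000_000,
                                          5_000_000, "chr1", 5_000_000 + sign * d))
        out = directional_asymmetry(pd.DataFrame(rows), oriented=True)
        assert np.allclose(out["ratio"].dropna(), 1.0, atol=0.15)

    def test_trans_contacts_excluded(self):
        rows = [_full_contact_row("t", "chr1", "+", 100, 100, "chr2", 500)]
        out = directional_asymmetry(pd.DataFrame(rows))
        assert out["downstream"].sum() == 0 and out["upstream"].sum() == 0


class TestScaling:
    def test_uniform_cis_contacts_give_flat_curve(self, rng):
        n = 60_000
        src = rng.integers(4_000_000, 6_000_000, size=n)
        tgt = rng.integers(0, 10_000_000, size=n)
        pairs = pd.DataFrame({"chrom1": "chr1", "pos1": src,
                              "chrom2": "chr1", "pos2": tgt})
        curve = scaling_curve(pairs, {"chr1": 10_000_000})
        m = (curve.distances >= 100_000) & (curve.distances <= 3_000_000) \
            & (curve.probability > 0)
        vals = curve.probability[m]
        assert vals.std() / vals.mean() < 0.1

    def test_bin_pair_count_non_increasing_multichrom(self, rng):
        sizes = {"chr1": 10_000_000, "chr2": 4_000_000}
        src_c = rng.choice(["chr1", "chr2"], size=2000)
        src_p = np.array([rng.integers(0, sizes[c]) for c in src_c])
        pairs = pd.DataFrame({"chrom1": src_c, "pos1": src_p,
                              "chrom2": src_c, "pos2": src_p})
        curve = scaling_curve(pairs, sizes)
        assert np.all(np.diff(curve.n_bin_pairs[1:]) <= 0)


class TestCisTrans:
    def _library(self, exon_trans, intron_trans, rng, n=2000):
        # two exons totalling 5000 nt and one 5000-nt intron
        genes = gene_frame([{
            "gene_id": "g", "name": "G", "biotype": "protein_coding",
            "chrom": "chr1", "strand": "+", "start": 0, "end": 10_000,
            "exons": [(0, 4000), (9000, 10_000)],
        }])
        rows, assign = [], []
        for i in range(n):
            in_exon = i % 2 == 0
            pos = int(rng.integers(0, 3980)) if in_exon else int(rng.integers(4000, 8980))
            rate = exon_trans if in_exon else intron_trans
            trans = rng.random() < rate
            chrom = "chr2" if trans else "chr1"
            anchor = int(rng.integers(0, 1_000_000))
            rows.append(_full_contact_row(f"r{i}", "chr1", "+", pos, pos + 19,
                                          chrom, anchor))
            assign.append("g")
        contacts = pd.DataFrame(rows)
        classified = classify_contacts(contacts, pd.Series(assign), genes)
        return contacts, classified, genes

    def test_all_cis_library(self, rng):
        contacts, classified, genes = self._library(0.0, 0.0, rng, n=400)
        out = cis_trans_summary(contacts, classified).set_index("part_class")
        assert out.loc["exon", "cis_fraction"] == 1.0
        assert out.loc["intron", "cis_fraction"] == 1.0

    def test_class_specific_trans_rates_recovered(self, rng):
        contacts, classified, genes = self._library(0.4, 0.2, rng)
        out = cis_trans_summary(contacts, classified).set_index("part_class")
        assert out.loc["exon", "trans_fraction"] > out.loc["intron", "trans_fraction"]

    def test_equal_density_gives_unit_exon_intron_ratio(self, rng):
        contacts, classified, genes = self._library(0.0, 0.0, rng, n=4000)
        out = contacts_per_nt(classified, genes).set_index("part_class")
        ratio = out.loc["exon", "contacts_per_nt"] / out.loc["intron", "contacts_per_nt"]
        assert ratio == pytest.approx(1.0, rel=0.1)
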