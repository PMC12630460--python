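"""Structure standardization, region grouping, filtering, and table IO."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import phytodiv as pv
from phytodiv.chem import RDKitBackend
from phytodiv.datamodel import PATHWAYS, CompoundOccurrence, Fingerprint


@pytest.fixture(scope="module")
def backend() -> RDKitBackend:
    return RDKitBackend()


class TestStandardize:
    def test_largest_fragment_kept(self, backend):
        assert pv.standardize_structure("CCO.Cl", backend) == "CCO"

    def test_single_fragment_unchanged(self, backend):
        assert pv.standardize_structure("CCO", backend) == "CCO"

    def test_salt_counterion_dropped_by_heavy_atom_count(self, backend):
        # acetate (4 heavy atoms) beats sodium (1): oracle is RDKit's own
        # canonical form of the bare anion
        from rdkit import Chem

        expected = Chem.MolToSmiles(Chem.MolFromSmiles("CC(=O)[O-]"))
        assert pv.standardize_structure("[Na+].CC(=O)[O-]", backend) == expected

    def test_unparseable_rejected_with_warning(self, backend, caplog):
        with caplog.at_level(logging.WARNING, logger="phytodiv"):
            assert pv.standardize_structure("not_a_smiles((", backend) is None
        assert "rejected" in caplog.text

    def test_idempotent_on_random_multifragment_strings(self, backend):
        frags = ["CCO", "c1ccccc1", "CC(=O)O", "[Na+]", "Cl", "CCN(CC)CC",
                 "O=C(O)c1ccccc1", "C1CCCCC1", "N", "CC(C)=O"]
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = int(rng.integers(1, 4))
            raw = ".".join(rng.choice(frags, size=k, replace=True))
            once = pv.standardize_structure(raw, backend)
            assert once is not None
            assert pv.standardize_structure(once, backend) == once


class TestRegionGrouping:
    def rec(self, taxon, structure, pathway="alkaloids", regions=("FIJ",)):
        return CompoundOccurrence(taxon=taxon, structure=structure,
                                  pathway=pathway, regions=frozenset(regions))

    def test_shared_compound_deduplicated(self):
        groups = pv.build_region_groups(
            [self.rec("sp1", "CCO"), self.rec("sp2", "CCO")]
        )
        (g,) = groups
        assert g.region == "FIJ" and len(g) == 1 and g.species == {"sp1", "sp2"}

    def test_multi_region_fan_out(self):
        recs = [self.rec("sp1", s, regions=("FIJ", "TON")) for s in ("A", "B", "C")]
        groups = pv.build_region_groups(recs)
        assert [g.region for g in groups] == ["FIJ", "TON"]
        assert all(len(g) == 3 for g in groups)

    def test_duplicate_structures_collapse(self):
        recs = [self.rec("sp1", s) for s in ("A", "B", "C", "A", "B")]
        (g,) = pv.build_region_groups(recs)
        assert len(g) == 3

    def test_pathway_conflict_first_wins(self, caplog):
        recs = [
            self.rec("sp1", "X", pathway="alkaloids"),
            self.rec("sp2", "X", pathway="terpenoids"),
        ]
        with caplog.at_level(logging.WARNING, logger="phytodiv"):
            (g,) = pv.build_region_groups(recs)
        assert g.compounds[0].pathway == "alkaloids"
        assert "conflict" in caplog.text

    def test_species_counted_once_per_native_region(self):
        rng = np.random.default_rng(5)
        regions = ["FIJ", "TON", "SAM", "VAN"]
        recs = []
        taxa = set()
        for i in range(40):
            taxon = f"sp{int(rng.integers(0, 12))}"
            taxa.add(taxon)
            native = tuple(rng.choice(regions, size=int(rng.integers(1, 3)), replace=False))
            recs.append(self.rec(taxon, f"S{i}", regions=native))
        groups = pv.build_region_groups(recs)
        assert sum(len(g.species) for g in groups) >= len(taxa)


class TestFilterGroups:
    def _groups(self, sizes):
        rng = np.random.default_rng(0)
        from conftest import make_group

        return [make_group(rng, n, region=f"R{i}") for i, n in enumerate(sizes)]

    def test_minimum_seven_compounds(self):
        kept = pv.filter_groups(self._groups([3, 7, 20]), min_size=7)
        assert [len(g) for g in kept] == [7, 20]

    def test_vacuous_filter(self):
        groups = self._groups([1, 2, 3])
        assert pv.filter_groups(groups, min_size=1) == groups

    def test_all_below_threshold_warns(self, caplog):
        with caplog.at_level(logging.WARNING, logger="phytodiv"):
            assert pv.filter_groups(self._groups([6] * 10), min_size=7) == []
        assert "fell below" in caplog.text

    def test_filter_composition(self):
        groups = self._groups([2, 4, 6, 8, 10])
        once = pv.filter_groups(groups, min_size=7)
        twice = pv.filter_groups(pv.filter_groups(groups, min_size=3), min_size=7)
        assert once == twice


class TestTables:
    def test_occurrence_round_trip(self, tmp_path, small_study):
        path = tmp_path / "occ.csv"
        pv.write_occurrence_table(small_study.occurrences, path)
        back = pv.read_occurrence_table(path)
        assert back == small_study.occurrences

    def test_uncategorised_rows_dropped(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text(
            "taxon,structure,pathway,regions\n"
            "sp1,AAA,alkaloids,FIJ\n"
            "sp2,BBB,,FIJ\n"
            "sp3,CCC,terpenoids,FIJ|TON\n"
        )
        records = pv.read_occurrence_table(path)
        assert len(records) == 2
        assert {r.structure for r in records} == {"AAA", "CCC"}

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("taxon,structure,regions\nsp1,AAA,FIJ\n")
        with pytest.raises(ValueError, match="pathway"):
            pv.read_occurrence_table(path)

    def test_unknown_region_code_warns_but_passes(self, tmp_path, caplog):
        path = tmp_path / "occ.csv"
        path.write_text("taxon,structure,pathway,regions\nsp1,AAA,alkaloids,ZZZ\n")
        with caplog.at_level(logging.WARNING, logger="phytodiv"):
            (rec,) = pv.read_occurrence_table(path)
        assert rec.regions == {"ZZZ"}
        assert "ZZZ" in caplog.text

    def test_fingerprint_round_trip(self, tmp_path):
        fps = {
            "AAA": Fingerprint(bits=frozenset({0, 5, 9}), n_bits=16),
            "BBB": Fingerprint(bits=frozenset({1}), n_bits=16),
        }
        path = tmp_path / "fp.csv"
        pv.write_fingerprint_table(fps, path)
        assert pv.read_fingerprint_table(path) == fps

    def test_diversity_nulls_serialize_as_empty_cells(self, tmp_path):
        prof = pv.DiversityProfile(region="FIJ", N=9, J=None, H=1.5)
        path = tmp_path / "div.csv"
        pv.write_diversity_table([prof], path)
        lines = path.read_text().splitlines()
        cols = lines[0].split(",")
        vals = lines[1].split(",")
        assert vals[cols.index("J")] == ""
        back = pv.read_diversity_table(path)
        assert back.loc[0, "H"] == pytest.approx(1.5)


class TestDomainTypes:
    def test_invalid_pathway_rejected(self):
        with pytest.raises(ValueError, match="pathway"):
            CompoundOccurrence("sp", "X", "not a pathway", frozenset({"FIJ"}))

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError, match="regions"):
            CompoundOccurrence("sp", "X", PATHWAYS[0], frozenset())

    def test_fingerprint_bit_range_checked(self):
        with pytest.raises(ValueError, match="range"):
            Fingerprint(bits=frozenset({20}), n_bits=16)

    def test_known_region_codes_include_common_codes(self):
        codes = pv.known_region_codes()
        assert {"FIJ", "TAS", "AGW", "GAL"} <= codes
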