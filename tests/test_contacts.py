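import math

import numpy as np
import pytest

from septevo.contacts import (
    Atom,
    ContactRecord,
    Residue,
    Structure,
    aggregate_interfaces,
    detect_contacts,
    group_frequency_profiles,
    interface_cluster,
    read_pdb,
    residue_interface_set,
    write_pdb,
)
from septevo.conservation import Alignment, map_to_reference
from septevo.errors import InvalidInputError, InvalidParameterError
from septevo.simulate import SimulationConfig, simulate_dimer_structures


def _carbon(x, y, z, name="CB", backbone=False):
    return Atom(name=name, element="C", x=x, y=y, z=z, radius=1.7, is_backbone=backbone)


def _structure(chain_a, chain_b, template="G:1-1"):
    return Structure(
        id="s", taxon="T01", template=template, chains={"A": chain_a, "B": chain_b}
    )


def _res(number, *atoms):
    return Residue(number, "ALA", tuple(atoms))


def brute_force_contacts(structure, probe=0.5):
    """Independent all-pairs oracle with plain python loops."""
    (na, nb) = sorted(structure.chains)
    found = {}
    for res_a in structure.chains[na]:
        for res_b in structure.chains[nb]:
            for atom_a in res_a.atoms:
                for atom_b in res_b.atoms:
                    d = math.dist(
                        (atom_a.x, atom_a.y, atom_a.z), (atom_b.x, atom_b.y, atom_b.z)
                    )
                    vdw = atom_a.radius + atom_b.radius
                    if d > vdw + probe:
                        continue
                    if atom_a.is_backbone and atom_b.is_backbone and d < vdw:
                        continue
                    key = (res_a.number, res_b.number)
                    gap = d - vdw
                    if key not in found or gap < found[key]:
                        found[key] = gap
    return found


class TestDetectContacts:
    def test_boundary_distance_is_contact(self):
        s = _structure([_res(1, _carbon(0, 0, 0))], [_res(2, _carbon(3.90, 0, 0))])
        contacts = detect_contacts(s)
        assert len(contacts) == 1
        assert contacts[0].min_gap == pytest.approx(0.5)

    def test_just_beyond_boundary_is_not(self):
        s = _structure([_res(1, _carbon(0, 0, 0))], [_res(2, _carbon(3.91, 0, 0))])
        assert detect_contacts(s) == []

    def test_backbone_backbone_clash_discarded(self):
        a = _carbon(0, 0, 0, name="CA", backbone=True)
        b = _carbon(2.0, 0, 0, name="CA", backbone=True)
        assert detect_contacts(_structure([_res(1, a)], [_res(2, b)])) == []

    def test_sidechain_overlap_not_discarded(self):
        a = _carbon(0, 0, 0, name="CB")
        b = _carbon(2.0, 0, 0, name="CB")
        contacts = detect_contacts(_structure([_res(1, a)], [_res(2, b)]))
        assert len(contacts) == 1

    def test_atom_pairs_collapse_to_residue_pairs(self):
        res_a = _res(10, _carbon(0, 0, 0), _carbon(1.0, 0, 0), _carbon(0, 1.0, 0))
        res_b = _res(55, _carbon(3.0, 0, 0))
        contacts = detect_contacts(_structure([res_a], [res_b]))
        assert len(contacts) == 1
        assert contacts[0].residue_a == ("A", 10)
        assert contacts[0].residue_b == ("B", 55)
        assert contacts[0].min_gap == pytest.approx(2.0 - 3.4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        def chain(n):
            return [
                _res(
                    i + 1,
                    *[
                        _carbon(*rng.uniform(0, 15, size=3), name="CB")
                        for _ in range(int(rng.integers(1, 4)))
                    ],
                )
                for i in range(n)
            ]
        s = _structure(chain(12), chain(12))
        got = {(c.residue_a[1], c.residue_b[1]): c.min_gap for c in detect_contacts(s)}
        want = brute_force_contacts(s)
        assert set(got) == set(want)
        for key in got:
            assert got[key] == pytest.approx(want[key], abs=1e-9)

    def test_chain_relabel_symmetry(self, rng):
        chain1 = [_res(i + 1, _carbon(*rng.uniform(0, 10, size=3))) for i in range(8)]
        chain2 = [_res(i + 1, _carbon(*rng.uniform(0, 10, size=3))) for i in range(8)]
        s1 = _structure(chain1, chain2)
        s2 = _structure(chain2, chain1)
        pairs1 = {(c.residue_a[1], c.residue_b[1]) for c in detect_contacts(s1)}
        pairs2 = {(c.residue_b[1], c.residue_a[1]) for c in detect_contacts(s2)}
        assert pairs1 == pairs2

    def test_probe_monotonicity(self, rng):
        chain1 = [_res(i + 1, _carbon(*rng.uniform(0, 12, size=3))) for i in range(10)]
        chain2 = [_res(i + 1, _carbon(*rng.uniform(0, 12, size=3))) for i in range(10)]
        s = _structure(chain1, chain2)
        small = {(c.residue_a, c.residue_b) for c in detect_contacts(s, 0.2)}
        large = {(c.residue_a, c.residue_b) for c in detect_contacts(s, 1.0)}
        assert small <= large

    def test_wrong_chain_count_rejected(self):
        with pytest.raises(InvalidInputError):
            Structure(id="x", taxon="t", template="G:1-1", chains={"A": []})


class TestResidueInterfaceSet:
    def test_dedup_across_atom_hits(self):
        contacts = [
            ContactRecord(("A", 10), ("B", 55), -0.1, "G"),
            ContactRecord(("A", 10), ("B", 55), 0.2, "G"),
        ]
        assert residue_interface_set(contacts) == {("A", 10), ("B", 55)}

    def test_empty(self):
        assert residue_interface_set([]) == set()


class TestAggregateInterfaces:
    def test_max_over_templates_and_threshold(self):
        sets = {}
        for i in range(12):
            sets[(f"T{i:02d}", "NC:1-2")] = {("A", 100)}
        for i in range(7):
            sets[(f"T{i:02d}", "NC:2-2")] = {("A", 100)}
        out = aggregate_interfaces(sets, n_taxa=17, min_taxa=10)
        (c,) = out
        assert c.max_count == 12
        assert c.proportion == pytest.approx(12 / 17)
        assert c.consensus

    def test_nine_of_seventeen_everywhere_fails(self):
        sets = {}
        for template in ("G:1-1", "G:2-2", "G:1-2"):
            for i in range(9):
                sets[(f"T{i:02d}", template)] = {("B", 40)}
        out = aggregate_interfaces(sets, n_taxa=17, min_taxa=10)
        assert not out[0].consensus

    def test_min_taxa_monotonicity(self):
        sets = {(f"T{i:02d}", "G:1-1"): {("A", 7)} for i in range(11)}
        loose = aggregate_interfaces(sets, n_taxa=17, min_taxa=10)
        strict = aggregate_interfaces(sets, n_taxa=17, min_taxa=12)
        assert loose[0].consensus and not strict[0].consensus

    def test_reference_mapping_drops_unmappable(self):
        sets = {("T01", "G:1-1"): {("A", 3), ("A", 4)}}
        ref_maps = {"T01": {3: 30}}  # residue 4 unmappable
        out = aggregate_interfaces(sets, ref_maps, n_taxa=17, min_taxa=1)
        assert [c.position for c in out] == [30]

    def test_planted_recovery_with_dropout(self):
        cfg = SimulationConfig(contact_dropout={("NC", 45): 8})
        structures, truth = simulate_dimer_structures(cfg, seed=3)
        sets = {
            (s.taxon, s.template): residue_interface_set(detect_contacts(s))
            for s in structures
        }
        out = aggregate_interfaces(sets, n_taxa=17, min_taxa=10)
        got = {(c.interface, c.position) for c in out if c.consensus}
        assert truth.true_interface - got == {("NC", 45)}


class TestGroupFrequencyProfiles:
    def test_frequencies_and_information_content(self):
        aln = Alignment({"a": "AAG", "b": "AVG", "g5": "CCC"})
        groups = {"a": "G1", "b": "G1", "g5": "G5"}
        ref_map = map_to_reference(aln, "a")
        profiles = group_frequency_profiles(aln, groups, [1, 2, 3], ref_map)
        g1 = profiles["G1"]
        assert g1.loc[1, "A"] == pytest.approx(1.0)
        assert g1.loc[1, "information"] == pytest.approx(2.0)
        assert g1.loc[2, "A"] == pytest.approx(0.5)
        assert g1.loc[2, "V"] == pytest.approx(0.5)
        assert g1.loc[2, "information"] == pytest.approx(1.0)

    def test_row_frequencies_sum_to_one_with_gap(self):
        aln = Alignment({"a": "A-", "b": "AV"})
        ref_map = map_to_reference(aln, "b")
        profiles = group_frequency_profiles(aln, {"a": "G1", "b": "G1"}, [2], ref_map)
        row = profiles["G1"].loc[2]
        aa_sum = sum(row[c] for c in "ACDEFGHIKLMNPQRSTVWY")
        assert aa_sum == pytest.approx(1.0)
        assert row["gap"] == pytest.approx(0.5)


class TestInterfaceCluster:
    def test_singleton(self):
        assert interface_cluster([129]) == [(129, 129)]

    def test_gap_arithmetic_merges_run(self):
        assert interface_cluster([209, 210, 211, 214], max_gap=3) == [(209, 214)]

    def test_distant_positions_split(self):
        assert interface_cluster([129, 209], max_gap=3) == [(129, 129), (209, 209)]

    def test_negative_gap_rejected(self):
        with pytest.raises(InvalidParameterError):
            interface_cluster([1], max_gap=-1)


class TestPdbRoundTrip:
    def test_write_read_preserves_geometry(self, tmp_path, default_config):
        structures, _ = simulate_dimer_structures(default_config, seed=1)
        s = structures[0]
        path = tmp_path / "dimer.pdb"
        write_pdb(s, str(path))
        again = read_pdb(str(path), taxon=s.taxon, template=s.template)
        assert set(again.chains) == {"A", "B"}
        assert len(again.chains["A"]) == len(s.chains["A"])
        a0 = s.chains["A"][0].atoms[0]
        b0 = again.chains["A"][0].atoms[0]
        assert (b0.x, b0.y, b0.z) == pytest.approx((a0.x, a0.y, a0.z), abs=1e-3)
        assert b0.radius == pytest.approx(1.7)
        got = {(c.residue_a, c.residue_b) for c in detect_contacts(again)}
        want = {(c.residue_a, c.residue_b) for c in detect_contacts(s)}
        assert got == want
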