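"""Structure: index maps, synthetic masks, adjacency loading, feedback wiring."""

import numpy as np
import pytest

from wormmotor.connectome import (A_CLASSES, B_CLASSES, CLASS_ORDER,
                                  ConnectomeMask, NeuronIndexMap,
                                  load_adjacency, proprioceptive_wiring,
                                  synthesize_connectome)


class TestNeuronIndexMap:
    def test_standard_counts(self, standard_map):
        assert standard_map.n_neurons == 69
        assert standard_map.n_muscles == 95
        assert standard_map.n_commands == 10

    def test_class_ranges_partition_neurons(self, standard_map):
        ranges = standard_map.class_ranges
        covered = np.zeros(standard_map.n_neurons, dtype=int)
        for a, b in ranges.values():
            covered[a:b] += 1
        assert (covered == 1).all()
        # the published global numbering: DA 1-8 ... AS 59-69 (1-based)
        assert ranges["DA"] == (0, 8)
        assert ranges["DD"] == (16, 22)
        assert ranges["VA"] == (22, 34)
        assert ranges["AS"] == (58, 69)

    def test_polarity_partition(self, standard_map):
        exc = standard_map.excitatory
        cls = standard_map.neuron_class
        assert set(cls[exc]) == {"DA", "DB", "VA", "VB", "AS"}
        assert set(cls[~exc]) == {"DD", "VD"}

    def test_muscle_rows_partition(self, standard_map):
        rows = standard_map.muscle_rows
        covered = np.zeros(95, dtype=int)
        for a, b in rows.values():
            covered[a:b] += 1
        assert (covered == 1).all()
        assert rows["RV"][1] - rows["RV"][0] == 23

    def test_segment_index_reaches_tail_on_short_row(self, standard_map):
        q = standard_map.segment_of_muscle
        a, b = standard_map.muscle_rows["RV"]
        assert q[b - 1] == 24          # last right-ventral cell covers the tail
        assert q[a] == 1
        assert standard_map.muscle_at("RV", 24) == b - 1
        assert standard_map.muscle_at("RV", 23) is None

    def test_scaled_map_keeps_all_classes(self):
        imap = NeuronIndexMap.scaled(8)
        assert set(imap.class_counts) == set(CLASS_ORDER)
        assert all(v >= 1 for v in imap.class_counts.values())
        assert imap.n_segments == 8

    def test_json_roundtrip(self, standard_map):
        back = NeuronIndexMap.from_json(standard_map.to_json())
        assert back == standard_map


class TestSynthesizeConnectome:
    def test_deterministic_under_seed(self, tiny_map):
        m1 = synthesize_connectome(tiny_map, seed=5, locality_span=2,
                                   proprio_span=2)
        m2 = synthesize_connectome(tiny_map, seed=5, locality_span=2,
                                   proprio_span=2)
        for f in ("syn_nn", "syn_nm", "syn_mn", "syn_in",
                  "gap_nn", "gap_mn", "gap_mm"):
            assert np.array_equal(getattr(m1, f), getattr(m2, f))

    def test_gap_masks_symmetric_no_diagonal(self, tiny_mask):
        tiny_mask.validate()
        assert np.array_equal(tiny_mask.gap_nn, tiny_mask.gap_nn.T)
        assert not tiny_mask.gap_nn.diagonal().any()
        assert not tiny_mask.gap_mm.diagonal().any()

    def test_locality_span_bounds_connections(self, standard_map):
        span = 3
        mask = synthesize_connectome(standard_map, locality_span=span, seed=1)
        anchors = mask.index_map.anchor_segments()
        q = mask.index_map.segment_of_muscle
        u_idx, j_idx = np.nonzero(mask.syn_nm)
        assert (np.abs(q[u_idx] - anchors[j_idx]) <= span).all()

    def test_full_density_fills_allowed_blocks(self, standard_map):
        mask = synthesize_connectome(standard_map, density=1.0,
                                     locality_span=24, seed=0)
        # the cross-inhibition wiring: ventral cholinergics drive every
        # DD, dorsal cholinergics every VD — and never the same side
        va_vb = np.concatenate([standard_map.class_indices("VA"),
                                standard_map.class_indices("VB")])
        dorsal_chol = np.concatenate([standard_map.class_indices(c)
                                      for c in ("DA", "DB", "AS")])
        dd = standard_map.class_indices("DD")
        vd = standard_map.class_indices("VD")
        assert mask.syn_nn[np.ix_(dd, va_vb)].all()
        assert mask.syn_nn[np.ix_(vd, dorsal_chol)].all()
        assert not mask.syn_nn[np.ix_(dd, dorsal_chol)].any()
        assert not mask.syn_nn[np.ix_(vd, va_vb)].any()

    def test_muscle_gap_chain_present(self, tiny_mask):
        imap = tiny_mask.index_map
        for row, (a, b) in imap.muscle_rows.items():
            for u in range(a, b - 1):
                assert tiny_mask.gap_mm[u, u + 1]

    def test_polarity_structure(self, tiny_mask):
        # chemical neuron->neuron synapses only run between the
        # cholinergic and GABAergic groups, never within
        exc = tiny_mask.index_map.excitatory
        assert not tiny_mask.syn_nn[np.ix_(exc, exc)].any()
        assert not tiny_mask.syn_nn[np.ix_(~exc, ~exc)].any()

    def test_save_load_roundtrip(self, tiny_mask, tmp_path):
        p = tmp_path / "mask.npz"
        tiny_mask.save(p)
        back = ConnectomeMask.load(p)
        for f in ("syn_nn", "syn_nm", "syn_mn", "syn_in",
                  "gap_nn", "gap_mn", "gap_mm"):
            assert np.array_equal(getattr(back, f), getattr(tiny_mask, f))
        assert back.index_map == tiny_mask.index_map
        assert back.proprioceptive == tiny_mask.proprioceptive


class TestProprioceptiveWiring:
    def test_matches_independent_enumeration(self, standard_map):
        """Brute-force enumeration over neurons, rows, and segments."""
        imap = standard_map
        S = 7
        anchors = imap.anchor_segments()
        cls = imap.neuron_class
        expected = set()
        for i in range(imap.n_neurons):
            if cls[i] in B_CLASSES:
                segs = [anchors[i] + d for d in range(1, S + 1)]
            elif cls[i] in A_CLASSES:
                segs = [anchors[i] - d for d in range(1, S + 1)]
            else:
                continue
            rows = ("LD", "RD") if cls[i][0] == "D" else ("LV", "RV")
            for row in rows:
                for s in segs:
                    if 1 <= s <= 24:
                        u = imap.muscle_at(row, s)
                        if u is not None:
                            expected.add((i, u))
        got = set(proprioceptive_wiring(imap, S=S))
        assert got == expected
        # mid-body B-class neurons sense S muscles per row
        db = imap.class_indices("DB")
        mid = db[len(db) // 2]
        per_row = sum(1 for (i, u) in got
                      if i == mid and imap.muscle_row_name[u] == "LD")
        assert per_row == S

    def test_head_a_class_neuron_has_no_anterior_muscles(self):
        imap = NeuronIndexMap.scaled(4)
        pairs = proprioceptive_wiring(imap, S=2)
        anchors = imap.anchor_segments()
        for i in imap.class_indices("DA"):
            if anchors[i] == 1:
                assert not any(p[0] == i for p in pairs)

    def test_pairs_present_in_synthesized_mask(self, tiny_mask):
        for i, u in proprioceptive_wiring(tiny_mask.index_map, S=2):
            assert tiny_mask.syn_mn[i, u]


class TestLoadAdjacency:
    # A tiny synthetic adjacency table in the wormwiring dialect:
    # rows = presynaptic cells, columns = postsynaptic cells, counts.
    SYN = (",DA01,DD01,MDL08,MDL09\n"
           "DA01,0,2,3,0\n"
           "DD01,1,0,2,0\n"
           "AVBL,4,0,0,0\n"
           "RIML,1,1,0,0\n")
    GAP = (",DA01,DD01,MDL08,MDL09\n"
           "DA01,0,1,0,0\n"
           "DD01,0,0,0,0\n"
           "MDL08,0,0,0,3\n"
           "MDL09,0,0,3,0\n")

    def test_counts_become_mask_entries(self, standard_map):
        mask = load_adjacency(self.SYN, self.GAP, standard_map,
                              include_proprioceptive=False)
        imap = standard_map
        da1 = imap.class_indices("DA")[0]
        dd1 = imap.class_indices("DD")[0]
        mdl8 = imap.muscle_at("LD", 8)
        mdl9 = imap.muscle_at("LD", 9)
        assert mask.syn_nn[dd1, da1]          # DA01 -> DD01, count 2
        assert mask.syn_nm[mdl8, da1]         # DA01 -> MDL08, count 3
        assert not mask.syn_nm[mdl9, da1]     # count 0 stays false
        assert mask.syn_in[da1, 2]            # AVBL is forward command 3
        assert mask.gap_mm[mdl8, mdl9] and mask.gap_mm[mdl9, mdl8]

    def test_gap_symmetrized_by_or(self, standard_map):
        mask = load_adjacency(self.SYN, self.GAP, standard_map,
                              include_proprioceptive=False)
        imap = standard_map
        da1 = imap.class_indices("DA")[0]
        dd1 = imap.class_indices("DD")[0]
        # DA01-DD01 gap listed one-way only; must come back symmetric
        assert mask.gap_nn[da1, dd1] and mask.gap_nn[dd1, da1]

    def test_cells_outside_model_dropped(self, standard_map):
        # RIML rows are silently dropped (logged), not an error
        mask = load_adjacency(self.SYN, self.GAP, standard_map,
                              include_proprioceptive=False)
        assert mask.syn_nn.sum() == 2

    def test_malformed_cell_name_raises(self, standard_map):
        bad = self.SYN.replace("RIML", "##bad")
        with pytest.raises(ValueError, match="cell name"):
            load_adjacency(bad, self.GAP, standard_map)

    def test_proprioceptive_union(self, standard_map):
        mask = load_adjacency(self.SYN, self.GAP, standard_map,
                              include_proprioceptive=True)
        assert mask.proprioceptive
        for i, u in mask.proprioceptive:
            assert mask.syn_mn[i, u]
        mask.validate()
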