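"""Network structure of the C. elegans ventral-cord motor circuit.

The model circuit contains the seven body-wall motor-neuron classes
(DA, DB, DD, VA, VB, VD, AS; 69 cells in the full animal), the 95
body-wall muscle cells arranged in four longitudinal rows, and ten
binary command-neuron input lines (4 forward: PVCL/R, AVBL/R; 6
backward: AVAL/R, AVDL/R, AVEL/R).  This module defines

* :class:`NeuronIndexMap` — the index bookkeeping (class ranges, muscle
  rows, head-to-tail segment positions), for the full-size circuit and
  for proportionally scaled-down instances;
* :class:`ConnectomeMask` — boolean support matrices saying which
  synaptic / gap-junction entries are structurally allowed;
* :func:`load_adjacency` — build masks from adjacency-matrix tables in
  the wormwiring dialect (cell-name keyed contact counts);
* :func:`synthesize_connectome` — a generative stand-in with the same
  qualitative class structure, so the pipeline runs without any
  downloaded data;
* :func:`proprioceptive_wiring` — the muscle→neuron feedback pairs
  standing in for stretch-receptive processes of A- and B-class
  neurons.

All arrays are 0-indexed; docstrings quote the field's 1-based cell
numbering where it helps.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Motor-neuron classes in global index order.
CLASS_ORDER = ("DA", "DB", "DD", "VA", "VB", "VD", "AS")

#: Cholinergic (excitatory) vs GABAergic (inhibitory) classes.
EXCITATORY_CLASSES = frozenset({"DA", "DB", "VA", "VB", "AS"})
INHIBITORY_CLASSES = frozenset({"DD", "VD"})

#: A-class neurons drive backward crawling, B-class forward.
A_CLASSES = ("DA", "VA")
B_CLASSES = ("DB", "VB")

#: Muscle rows in global index order: left-dorsal, right-dorsal,
#: left-ventral, right-ventral.
ROW_ORDER = ("LD", "RD", "LV", "RV")
DORSAL_ROWS = ("LD", "RD")
VENTRAL_ROWS = ("LV", "RV")

#: Full-animal class sizes used throughout (sum = 69).
STANDARD_CLASS_COUNTS = {
    "DA": 8, "DB": 8, "DD": 6, "VA": 12, "VB": 11, "VD": 13, "AS": 11,
}
#: Full-animal muscle-row lengths (sum = 95; the right-ventral row has
#: one fewer cell than the other three).
STANDARD_ROW_LENGTHS = {"LD": 24, "RD": 24, "LV": 24, "RV": 23}

FORWARD_COMMAND_NAMES = ("PVCL", "PVCR", "AVBL", "AVBR")
BACKWARD_COMMAND_NAMES = ("AVAL", "AVAR", "AVDL", "AVDR", "AVEL", "AVER")

_MUSCLE_ROW_PREFIX = {"MDL": "LD", "MDR": "RD", "MVL": "LV", "MVR": "RV"}


@dataclass(frozen=True)
class NeuronIndexMap:
    """Index conventions for a (possibly scaled) motor circuit.

    Parameters
    ----------
    class_counts
        Number of neurons per motor-neuron class, keyed by class name in
        :data:`CLASS_ORDER`.  Classes may be absent or zero for reduced
        test circuits.
    row_lengths
        Number of muscle cells per row, keyed by row name in
        :data:`ROW_ORDER`.
    n_segments
        Number of head-to-tail body segments the muscle rows span
        (24 in the full animal).
    n_forward, n_backward
        Number of forward / backward command-input lines.
    """

    class_counts: Mapping[str, int]
    row_lengths: Mapping[str, int]
    n_segments: int = 24
    n_forward: int = 4
    n_backward: int = 6

    def __post_init__(self):
        for name in self.class_counts:
            if name not in CLASS_ORDER:
                raise ValueError(f"unknown motor-neuron class {name!r}")
        for name in self.row_lengths:
            if name not in ROW_ORDER:
                raise ValueError(f"unknown muscle row {name!r}")
        if max(self.row_lengths.values(), default=0) > self.n_segments:
            raise ValueError("muscle row longer than the number of segments")

    # -- construction ---------------------------------------------------

    @classmethod
    def standard(cls) -> "NeuronIndexMap":
        """The full-animal map: 69 motor neurons, 95 muscles, 24 segments."""
        return cls(dict(STANDARD_CLASS_COUNTS), dict(STANDARD_ROW_LENGTHS))

    @classmethod
    def scaled(cls, n_segments: int) -> "NeuronIndexMap":
        """A proportionally shrunk circuit spanning ``n_segments`` segments.

        Class sizes scale with ``n_segments / 24`` (at least one cell per
        class); three muscle rows have ``n_segments`` cells and the
        fourth one fewer, mirroring the full animal's asymmetry.
        """
        if n_segments < 2:
            raise ValueError("need at least 2 segments")
        frac = n_segments / 24.0
        counts = {k: max(1, round(v * frac)) for k, v in STANDARD_CLASS_COUNTS.items()}
        rows = {"LD": n_segments, "RD": n_segments, "LV": n_segments,
                "RV": max(1, n_segments - 1)}
        return cls(counts, rows, n_segments=n_segments)

    # -- sizes ----------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return sum(self.class_counts.values())

    @property
    def n_muscles(self) -> int:
        return sum(self.row_lengths.values())

    @property
    def n_commands(self) -> int:
        return self.n_forward + self.n_backward

    # -- neuron-side lookups --------------------------------------------

    @property
    def class_ranges(self) -> dict[str, tuple[int, int]]:
        """0-based half-open ``[start, stop)`` index range per class."""
        out, start = {}, 0
        for name in CLASS_ORDER:
            c = self.class_counts.get(name, 0)
            if c:
                out[name] = (start, start + c)
                start += c
        return out

    def class_indices(self, name: str) -> np.ndarray:
        start, stop = self.class_ranges.get(name, (0, 0))
        return np.arange(start, stop)

    @property
    def neuron_class(self) -> np.ndarray:
        """Array of class names, one per neuron."""
        out = np.empty(self.n_neurons, dtype=object)
        for name, (a, b) in self.class_ranges.items():
            out[a:b] = name
        return out

    @property
    def excitatory(self) -> np.ndarray:
        """Boolean: presynaptic sign constraint is >= 0 for these neurons."""
        cls_of = self.neuron_class
        return np.array([c in EXCITATORY_CLASSES for c in cls_of])

    @property
    def inhibitory(self) -> np.ndarray:
        return ~self.excitatory

    def neuron_names(self) -> list[str]:
        return [f"{c}{r + 1:02d}" for c in CLASS_ORDER
                for r in range(self.class_counts.get(c, 0))]

    def anchor_segments(self) -> np.ndarray:
        """Body segment each neuron sits at, one entry per neuron (1-based).

        Neurons of a class are spread evenly from head to tail: the r-th
        of C cells anchors at ``round(r * n_segments / C)`` (clipped to
        at least segment 1).  This is the convention used both by the
        synthetic connectome generator and by the proprioceptive wiring.
        """
        S = self.n_segments
        anchors = np.empty(self.n_neurons, dtype=int)
        for name, (a, b) in self.class_ranges.items():
            C = b - a
            for r in range(C):
                anchors[a + r] = min(S, max(1, round((r + 1) * S / C)))
        return anchors

    # -- muscle-side lookups --------------------------------------------

    @property
    def muscle_rows(self) -> dict[str, tuple[int, int]]:
        """0-based half-open index range per muscle row."""
        out, start = {}, 0
        for name in ROW_ORDER:
            c = self.row_lengths.get(name, 0)
            if c:
                out[name] = (start, start + c)
                start += c
        return out

    def row_indices(self, row: str) -> np.ndarray:
        a, b = self.muscle_rows.get(row, (0, 0))
        return np.arange(a, b)

    @property
    def muscle_row_name(self) -> np.ndarray:
        out = np.empty(self.n_muscles, dtype=object)
        for name, (a, b) in self.muscle_rows.items():
            out[a:b] = name
        return out

    @property
    def muscle_is_dorsal(self) -> np.ndarray:
        return np.array([r in DORSAL_ROWS for r in self.muscle_row_name])

    @property
    def segment_of_muscle(self) -> np.ndarray:
        """1-based head-to-tail segment index q of every muscle.

        Within a row the p-th cell sits at segment p; the last cell of a
        row shorter than ``n_segments`` stands in for the terminal
        segment, so every row reaches the tail.
        """
        q = np.empty(self.n_muscles, dtype=int)
        for name, (a, b) in self.muscle_rows.items():
            L = b - a
            q[a:b] = np.arange(1, L + 1)
            if L < self.n_segments:
                q[b - 1] = self.n_segments
        return q

    def muscle_at(self, row: str, segment: int) -> int | None:
        """Global index of the cell of ``row`` at ``segment``, or None."""
        a, b = self.muscle_rows.get(row, (0, 0))
        L = b - a
        if L == 0 or not 1 <= segment <= self.n_segments:
            return None
        if L < self.n_segments:
            # cells 1..L-1 sit at segments 1..L-1; the last cell covers
            # the terminal segment (consistent with segment_of_muscle)
            if segment == self.n_segments:
                return b - 1
            if segment >= L:
                return None
        return a + segment - 1

    def muscle_names(self) -> list[str]:
        inv = {v: k for k, v in _MUSCLE_ROW_PREFIX.items()}
        return [f"{inv[row]}{p + 1:02d}"
                for row in ROW_ORDER
                for p in range(self.row_lengths.get(row, 0))]

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "class_counts": dict(self.class_counts),
            "row_lengths": dict(self.row_lengths),
            "n_segments": self.n_segments,
            "n_forward": self.n_forward,
            "n_backward": self.n_backward,
        })

    @classmethod
    def from_json(cls, text: str) -> "NeuronIndexMap":
        d = json.loads(text)
        return cls(d["class_counts"], d["row_lengths"], d["n_segments"],
                   d["n_forward"], d["n_backward"])


@dataclass
class ConnectomeMask:
    """Boolean support of every trainable connection family.

    Matrix orientation follows the dynamics: the first axis is the
    postsynaptic (receiving) cell, the second the presynaptic (sending)
    cell.  ``syn_mn`` (muscle→neuron) holds the union of any
    adjacency-derived entries and the proprioceptive-feedback pairs, so
    each (neuron, muscle) influence is represented exactly once.
    """

    index_map: NeuronIndexMap
    syn_nn: np.ndarray   # (J, J) neuron <- neuron
    syn_nm: np.ndarray   # (M, J) muscle <- neuron
    syn_mn: np.ndarray   # (J, M) neuron <- muscle (incl. proprioceptive)
    syn_in: np.ndarray   # (J, P) neuron <- command
    gap_nn: np.ndarray   # (J, J) symmetric, zero diagonal
    gap_mn: np.ndarray   # (J, M); the (M, J) transpose is implied
    gap_mm: np.ndarray   # (M, M) symmetric, zero diagonal
    proprioceptive: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        J, M, P = (self.index_map.n_neurons, self.index_map.n_muscles,
                   self.index_map.n_commands)
        shapes = {"syn_nn": (J, J), "syn_nm": (M, J), "syn_mn": (J, M),
                  "syn_in": (J, P), "gap_nn": (J, J), "gap_mn": (J, M),
                  "gap_mm": (M, M)}
        for name, want in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != want:
                raise ValueError(f"{name} has shape {arr.shape}, expected {want}")
            setattr(self, name, arr)

    def validate(self) -> None:
        """Raise if a structural invariant is violated."""
        if not np.array_equal(self.gap_nn, self.gap_nn.T):
            raise ValueError("gap_nn is not symmetric")
        if not np.array_equal(self.gap_mm, self.gap_mm.T):
            raise ValueError("gap_mm is not symmetric")
        if self.gap_nn.diagonal().any() or self.gap_mm.diagonal().any():
            raise ValueError("self gap junction on the diagonal")
        for i, u in self.proprioceptive:
            if not self.syn_mn[i, u]:
                raise ValueError(f"proprioceptive pair ({i}, {u}) missing from syn_mn")

    def n_synaptic(self) -> int:
        """Number of structurally allowed chemical-synapse entries."""
        return int(self.syn_nn.sum() + self.syn_nm.sum()
                   + self.syn_mn.sum() + self.syn_in.sum())

    def n_gap_pairs(self) -> int:
        """Number of unique gap-junction pairs (unordered within nn/mm)."""
        return int(np.triu(self.gap_nn, 1).sum() + self.gap_mn.sum()
                   + np.triu(self.gap_mm, 1).sum())

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write the masks and index map to a single ``.npz`` archive."""
        np.savez_compressed(
            path,
            syn_nn=self.syn_nn, syn_nm=self.syn_nm, syn_mn=self.syn_mn,
            syn_in=self.syn_in, gap_nn=self.gap_nn, gap_mn=self.gap_mn,
            gap_mm=self.gap_mm,
            proprioceptive=np.array(self.proprioceptive, dtype=int).reshape(-1, 2),
            index_map=np.frombuffer(self.index_map.to_json().encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "ConnectomeMask":
        with np.load(path) as z:
            imap = NeuronIndexMap.from_json(bytes(z["index_map"]).decode())
            return cls(
                index_map=imap,
                syn_nn=z["syn_nn"], syn_nm=z["syn_nm"], syn_mn=z["syn_mn"],
                syn_in=z["syn_in"], gap_nn=z["gap_nn"], gap_mn=z["gap_mn"],
                gap_mm=z["gap_mm"],
                proprioceptive=[tuple(p) for p in z["proprioceptive"]],
            )


# ---------------------------------------------------------------------------
# Proprioceptive feedback wiring
# ---------------------------------------------------------------------------

def proprioceptive_wiring(index_map: NeuronIndexMap, S: int = 7
                          ) -> list[tuple[int, int]]:
    """Muscle→neuron feedback pairs standing in for stretch reception.

    Each B-class neuron (DB, VB) receives the outputs of up to ``S``
    muscles *posterior* to its anchor segment, each A-class neuron (DA,
    VA) up to ``S`` muscles *anterior*; at the head and tail the span is
    clipped to the muscles that exist.  Dorsal-class neurons (D prefix)
    sense both dorsal rows, ventral-class neurons both ventral rows.

    Returns 0-based ``(neuron, muscle)`` pairs, ordered by neuron then
    muscle index.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    anchors = index_map.anchor_segments()
    cls_of = index_map.neuron_class
    pairs: list[tuple[int, int]] = []
    for i in range(index_map.n_neurons):
        c = cls_of[i]
        if c in B_CLASSES:
            offsets = range(1, S + 1)          # posterior
        elif c in A_CLASSES:
            offsets = range(-1, -S - 1, -1)    # anterior
        else:
            continue
        rows = DORSAL_ROWS if c.startswith("D") else VENTRAL_ROWS
        seen = set()
        for row in rows:
            for off in offsets:
                seg = anchors[i] + off
                if not 1 <= seg <= index_map.n_segments:
                    continue
                u = index_map.muscle_at(row, seg)
                if u is not None and u not in seen:
                    seen.add(u)
                    pairs.append((i, int(u)))
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# Synthetic connectome generator
# ---------------------------------------------------------------------------

_DENSITY_KEYS = ("nn", "nm", "mn", "in", "gap_nn", "gap_mn", "gap_mm")
DEFAULT_DENSITY = {
    "nn": 0.8,      # cholinergic <-> GABAergic chemical synapses
    "nm": 0.8,      # neuron -> muscle synapses
    "mn": 0.0,      # muscle -> neuron chemical synapses: none in the
                    # animal; feedback enters via the proprioceptive
                    # pairs, which are always added to syn_mn
    "in": 1.0,      # command -> neuron
    "gap_nn": 0.5,  # neuron-neuron gap junctions (beyond in-class chain)
    "gap_mn": 0.3,  # neuron-muscle gap junctions
    "gap_mm": 0.0,  # extra muscle-muscle gaps beyond the in-row chain
}

#: Muscle rows each class innervates: dorsal classes drive dorsal rows,
#: ventral classes ventral rows.
_CLASS_TARGET_ROWS = {
    "DA": DORSAL_ROWS, "DB": DORSAL_ROWS, "DD": DORSAL_ROWS, "AS": DORSAL_ROWS,
    "VA": VENTRAL_ROWS, "VB": VENTRAL_ROWS, "VD": VENTRAL_ROWS,
}


def synthesize_connectome(index_map: NeuronIndexMap,
                          density: float | Mapping[str, float] | None = None,
                          locality_span: int = 7,
                          seed: int = 0,
                          proprio_span: int = 7,
                          max_attempts: int = 5) -> ConnectomeMask:
    """Generate a connectivity mask with the motor circuit's class structure.

    The generator reproduces the qualitative wiring rules of the real
    ventral cord rather than any particular adjacency table: cholinergic
    neurons (A/B/AS classes) excite nearby muscles of their own side and
    the GABAergic D classes; D classes project back onto cholinergic
    neurons and muscles; every muscle row carries a nearest-neighbour
    gap-junction chain (so activity can spread between adjacent
    muscles); command lines reach the motor neurons directly.  "Nearby"
    means within ``locality_span`` body segments of a neuron's anchor
    segment.

    Parameters
    ----------
    density
        Bernoulli inclusion probability per connection family (keys of
        :data:`DEFAULT_DENSITY`); a scalar applies to every family.
    locality_span
        Maximum head-to-tail distance, in segments, of a chemical or gap
        connection.
    seed
        Seeds the mask draw; identical seeds give identical masks.
    proprio_span
        ``S`` of the proprioceptive wiring folded into ``syn_mn``.
    max_attempts
        A draw that leaves any muscle outside the head region (first 4
        segments) without a presynaptic motor neuron is rejected and
        redrawn; after this many failures an error is raised.

    Raises
    ------
    RuntimeError
        If no draw within ``max_attempts`` innervates every non-head
        muscle (such a target is untrainable).
    """
    if locality_span < 1:
        raise ValueError("locality_span must be >= 1")
    dens = dict(DEFAULT_DENSITY)
    if density is not None:
        if isinstance(density, Mapping):
            unknown = set(density) - set(_DENSITY_KEYS)
            if unknown:
                raise ValueError(f"unknown density keys: {sorted(unknown)}")
            dens.update(density)
        else:
            dens = {k: float(density) for k in _DENSITY_KEYS}
            dens["gap_mm"] = 0.0
    if not all(0.0 <= v <= 1.0 for v in dens.values()):
        raise ValueError("densities must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        mask = _draw_mask(index_map, dens, locality_span, rng, proprio_span)
        if _non_head_muscles_innervated(mask):
            mask.validate()
            return mask
    raise RuntimeError(
        "failed to innervate every non-head muscle; raise the 'nm' density")


def _non_head_muscles_innervated(mask: ConnectomeMask) -> bool:
    q = mask.index_map.segment_of_muscle
    body = q > 4  # first 4 segments per row are nerve-ring territory
    return bool(mask.syn_nm[body].any(axis=1).all())


def _draw_mask(imap, dens, span, rng, proprio_span) -> ConnectomeMask:
    J, M, P = imap.n_neurons, imap.n_muscles, imap.n_commands
    anchors = imap.anchor_segments()
    cls_of = imap.neuron_class
    q = imap.segment_of_muscle
    exc = imap.excitatory

    # segment distances
    d_nn = np.abs(anchors[:, None] - anchors[None, :])       # (J, J)
    d_nm = np.abs(q[:, None] - anchors[None, :])             # (M, J)

    # which muscle rows a neuron can reach (same dorsoventral side)
    row_of = imap.muscle_row_name
    reach = np.zeros((M, J), dtype=bool)
    for j in range(J):
        reach[:, j] = np.isin(row_of, _CLASS_TARGET_ROWS[cls_of[j]])

    # chemical synapses between neurons.  The D-class inhibition is
    # cross-wired as in the animal: ventral cholinergics (VA, VB) drive
    # DD (which inhibits dorsal muscles), dorsal cholinergics (DA, DB,
    # AS) drive VD (which inhibits ventral muscles) — the reciprocal
    # pattern that enforces dorsoventral antiphase.  D-class output back
    # onto cholinergic neurons is side-unspecific.
    chol = exc
    gaba = ~exc
    ventral_chol = np.isin(cls_of, ("VA", "VB"))
    dorsal_chol = chol & ~ventral_chol
    is_dd = cls_of == "DD"
    is_vd = cls_of == "VD"
    polarity_ok = ((ventral_chol[None, :] & is_dd[:, None])
                   | (dorsal_chol[None, :] & is_vd[:, None])
                   | (gaba[None, :] & chol[:, None]))
    syn_nn = polarity_ok & (d_nn <= span) & (rng.random((J, J)) < dens["nn"])
    np.fill_diagonal(syn_nn, False)

    # neuron -> muscle synapses, local and side-respecting
    syn_nm = reach & (d_nm <= span) & (rng.random((M, J)) < dens["nm"])

    # adjacency-style muscle -> neuron entries plus proprioceptive union
    syn_mn = (reach.T & (d_nm.T <= span)
              & (rng.random((J, M)) < dens["mn"]))
    pairs = proprioceptive_wiring(imap, S=proprio_span)
    for i, u in pairs:
        syn_mn[i, u] = True

    # command inputs
    syn_in = rng.random((J, P)) < dens["in"]

    # gap junctions: in-class nearest-rank chain always present,
    # plus random local symmetric extras
    gap_nn = np.zeros((J, J), dtype=bool)
    for name, (a, b) in imap.class_ranges.items():
        for i in range(a, b - 1):
            gap_nn[i, i + 1] = gap_nn[i + 1, i] = True
    extra = (d_nn <= span) & (rng.random((J, J)) < dens["gap_nn"])
    gap_nn |= extra | extra.T
    np.fill_diagonal(gap_nn, False)

    gap_mn = (reach.T & (d_nm.T <= span)
              & (rng.random((J, M)) < dens["gap_mn"]))

    gap_mm = np.zeros((M, M), dtype=bool)
    for name, (a, b) in imap.muscle_rows.items():
        for u in range(a, b - 1):
            gap_mm[u, u + 1] = gap_mm[u + 1, u] = True
    if dens["gap_mm"] > 0:
        d_mm = np.abs(q[:, None] - q[None, :])
        extra = (d_mm <= span) & (rng.random((M, M)) < dens["gap_mm"])
        gap_mm |= extra | extra.T
        np.fill_diagonal(gap_mm, False)

    return ConnectomeMask(imap, syn_nn, syn_nm, syn_mn, syn_in,
                          gap_nn, gap_mn, gap_mm, proprioceptive=pairs)


# ---------------------------------------------------------------------------
# Adjacency-table loading (wormwiring dialect)
# ---------------------------------------------------------------------------

_NEURON_RE = re.compile(r"^([A-Z]{2})0*(\d+)$")
_MUSCLE_RE = re.compile(r"^(MDL|MDR|MVL|MVR)0*(\d+)$")
_CELLNAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_/-]*$")


def _resolve_cell(name: str, imap: NeuronIndexMap):
    """Classify a cell name: ('neuron', idx) | ('muscle', idx) |
    ('command', idx) | ('other', None) | raises on malformed names."""
    name = str(name).strip()
    if name.upper() in FORWARD_COMMAND_NAMES:
        return "command", FORWARD_COMMAND_NAMES.index(name.upper())
    if name.upper() in BACKWARD_COMMAND_NAMES:
        return "command", imap.n_forward + BACKWARD_COMMAND_NAMES.index(name.upper())
    m = _MUSCLE_RE.match(name.upper())
    if m:
        row = _MUSCLE_ROW_PREFIX[m.group(1)]
        pos = int(m.group(2))
        a, b = imap.muscle_rows.get(row, (0, 0))
        if 1 <= pos <= b - a:
            return "muscle", a + pos - 1
        return "other", None
    m = _NEURON_RE.match(name.upper())
    if m and m.group(1) in CLASS_ORDER:
        rank = int(m.group(2))
        a, b = imap.class_ranges.get(m.group(1), (0, 0))
        if 1 <= rank <= b - a:
            return "neuron", a + rank - 1
        return "other", None
    if not _CELLNAME_RE.match(name):
        raise ValueError(f"malformed cell name: {name!r}")
    return "other", None


def _read_table(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if isinstance(table, str) and "\n" in table:
        return pd.read_csv(io.StringIO(table), sep=None, engine="python",
                           index_col=0)
    return pd.read_csv(table, sep=None, engine="python", index_col=0)


def load_adjacency(syn_table, gap_table, index_map: NeuronIndexMap | None = None,
                   include_proprioceptive: bool = True,
                   proprio_span: int = 7) -> ConnectomeMask:
    """Build a :class:`ConnectomeMask` from adjacency-count tables.

    Tables follow the wormwiring dialect: a delimited text matrix whose
    row labels are presynaptic (sending) cells, column labels
    postsynaptic (receiving) cells, and entries nonnegative contact
    counts; a mask entry is true iff the count is positive.  Cells
    outside the model (nerve-ring neurons, head muscles, …) are dropped
    with a logged count; names that are not plausible cell names raise.
    Gap-junction counts are symmetrized by logical OR (a warning is
    logged when the counts are asymmetric).

    Parameters
    ----------
    syn_table, gap_table
        Paths, file-like objects, CSV/TSV text, or DataFrames.
    index_map
        Defaults to the full-animal map.
    include_proprioceptive
        Fold the proprioceptive feedback pairs into ``syn_mn`` (they are
        part of the model's structure, not of the anatomical table).
    """
    imap = index_map or NeuronIndexMap.standard()
    J, M, P = imap.n_neurons, imap.n_muscles, imap.n_commands
    syn = _read_table(syn_table)
    gap = _read_table(gap_table)

    mats = {
        "syn_nn": np.zeros((J, J), dtype=bool),
        "syn_nm": np.zeros((M, J), dtype=bool),
        "syn_mn": np.zeros((J, M), dtype=bool),
        "syn_in": np.zeros((J, P), dtype=bool),
        "gap_nn": np.zeros((J, J), dtype=bool),
        "gap_mn": np.zeros((J, M), dtype=bool),
        "gap_mm": np.zeros((M, M), dtype=bool),
    }
    bad: list[str] = []
    dropped = 0

    def resolve(name):
        nonlocal dropped
        try:
            kind, idx = _resolve_cell(name, imap)
        except ValueError:
            bad.append(str(name))
            return "other", None
        if kind == "other":
            dropped += 1
        return kind, idx

    for which, df in (("syn", syn), ("gap", gap)):
        for pre_name, row in df.iterrows():
            pre_kind, pre = resolve(pre_name)
            for post_name, count in row.items():
                post_kind, post = resolve(post_name)
                if pd.isna(count) or float(count) <= 0:
                    continue
                if pre_kind == "other" or post_kind == "other":
                    continue
                key = _route(which, pre_kind, post_kind)
                if key is None:
                    continue
                if key == "syn_nn":
                    mats[key][post, pre] = True
                elif key == "syn_nm":
                    mats[key][post, pre] = True
                elif key == "syn_mn":
                    mats[key][post, pre] = True
                elif key == "syn_in":
                    mats[key][post, pre] = True
                elif key == "gap_nn":
                    mats[key][post, pre] = True
                elif key == "gap_mm":
                    mats[key][post, pre] = True
                elif key == "gap_mn":
                    i, u = (post, pre) if post_kind == "neuron" else (pre, post)
                    mats[key][i, u] = True
    if bad:
        raise ValueError(f"unresolvable cell names: {sorted(set(bad))}")
    if dropped:
        logger.info("dropped %d table entries involving cells outside the model",
                    dropped)

    if not np.array_equal(mats["gap_nn"], mats["gap_nn"].T):
        logger.warning("asymmetric neuron-neuron gap counts; symmetrizing by OR")
    mats["gap_nn"] |= mats["gap_nn"].T
    if not np.array_equal(mats["gap_mm"], mats["gap_mm"].T):
        logger.warning("asymmetric muscle-muscle gap counts; symmetrizing by OR")
    mats["gap_mm"] |= mats["gap_mm"].T
    np.fill_diagonal(mats["gap_nn"], False)
    np.fill_diagonal(mats["gap_mm"], False)

    pairs: list[tuple[int, int]] = []
    if include_proprioceptive:
        pairs = proprioceptive_wiring(imap, S=proprio_span)
        for i, u in pairs:
            mats["syn_mn"][i, u] = True

    mask = ConnectomeMask(imap, proprioceptive=pairs, **mats)
    mask.validate()
    return mask


def _route(which, pre_kind, post_kind):
    if which == "syn":
        table = {("neuron", "neuron"): "syn_nn",
                 ("neuron", "muscle"): "syn_nm",
                 ("muscle", "neuron"): "syn_mn",
                 ("command", "neuron"): "syn_in"}
    else:
        table = {("neuron", "neuron"): "gap_nn",
                 ("muscle", "muscle"): "gap_mm",
                 ("neuron", "muscle"): "gap_mn",
                 ("muscle", "neuron"): "gap_mn"}
    return table.get((pre_kind, post_kind))
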