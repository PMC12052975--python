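"""Deterministic generators for every input the analysis chain consumes.

Four families of synthetic data, each a pure function of (spec, seed):

* analytic landscapes emulating the free-energy archetypes of the study
  (overall-downhill substrate profiles, a non-substrate variant with an
  extra entry barrier between -1 and -0.5 nm, double wells);
* the transport phenotype table of the molecule x gate-variant grid;
* labeled contact-frequency panels with planted promoting / counteracting
  residue effects, either sampled directly or routed mechanistically
  through steered pulls on matched landscapes;
* taxon-structured full-size-ABCG-like sequence panels with the PDR
  signature motifs and the reference helix segments planted at known
  coordinates, plus truth tables sufficient to score every downstream
  stage.

Contact-frequency magnitudes are generator conventions (baseline 0.2,
effect 0.3): the study reports contact maps as color scales, not numbers,
so these defaults are chosen to make recovery neither trivial nor
impossible, and are exposed on the spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import LangevinParams, WallSpec
from .landscapes import Landscape
from .pulling import (ContactFrequencyTable, PullConfig, ResidueZone,
                      adjusted_contact_frequencies, run_constant_velocity_pull)
from .seqgate import AMINO_ACIDS, PDR_MOTIFS, SeqRecord

__all__ = [
    "make_landscape",
    "make_transport_labels",
    "PanelSpec",
    "make_pull_panel",
    "SequencePanelSpec",
    "SequencePanel",
    "make_sequence_panel",
    "make_reference_scaffold",
    "MOLECULES",
    "VARIANTS",
    "PROMOTE_RESIDUES",
    "COUNTERACT_RESIDUES",
]

MOLECULES = ("IBA", "CLX", "IAA", "IND")
VARIANTS = ("Wt", "L704F", "L704Y", "L704S", "L704A", "L704R", "L704D",
            "L704W", "A1357V")

PROMOTE_RESIDUES = ("I585", "F698", "L704", "L705", "Y1251", "A1252", "N1369")
COUNTERACT_RESIDUES = ("F589", "F592", "I1259", "N1260")
BACKGROUND_RESIDUES = ("F586", "T590", "S601", "G640", "A652", "T688", "A700",
                       "P710", "S800", "V900", "T1000", "A1100", "I1200",
                       "G1256", "S1300")

#: pathway coordinates (nm) of the residue zones used in mechanistic mode:
#: promoting residues cluster near the extracellular gate (> 1.3 nm),
#: counteracting ones in the entry / inner-leaflet region.
ZONE_CENTERS: Dict[str, float] = {
    "I585": 1.70, "F698": 1.75, "L704": 1.80, "L705": 1.85,
    "Y1251": 1.90, "A1252": 1.95, "N1369": 2.00,
    "F589": -1.00, "F592": -0.92, "I1259": -0.84, "N1260": -0.76,
}
ZONE_CENTERS.update({lab: c for lab, c in zip(
    BACKGROUND_RESIDUES, np.round(np.linspace(-0.50, 1.50, len(BACKGROUND_RESIDUES)), 2))})


# ---------------------------------------------------------------------------
# Landscapes

def make_landscape(archetype: str, params: Mapping | None = None,
                   seed: int = 0) -> Landscape:
    """Construct an analytic landscape archetype with exactly known profile.

    Archetypes: ``substrate_downhill`` (linear downhill trend from the
    intracellular entry to the extracellular gate with two sub-6 kJ/mol
    barriers), ``nonsubstrate_entry_barrier`` (the same plus a Gaussian
    barrier, default +8 kJ/mol, centered in [-1, -0.5]), ``double_well``,
    ``harmonic`` and ``flat``. All parameters are recorded on the returned
    object; ``seed`` is accepted for interface uniformity (the archetypes
    are deterministic).
    """
    p = dict(params or {})
    domain = p.pop("domain", (-1.5, 2.4))
    if archetype == "flat":
        return Landscape(kind="flat", domain=domain)
    if archetype == "harmonic":
        return Landscape(kind="harmonic",
                         params={"k": p.get("k", 10.0), "z0": p.get("z0", 0.0)},
                         domain=domain)
    if archetype == "double_well":
        return Landscape(kind="double_well",
                         params={"barrier": p.get("barrier", 12.0),
                                 "minima": p.get("minima", 0.8)},
                         domain=domain)
    if archetype == "substrate_downhill":
        slope = p.get("slope", -8.0)
        gaussians = tuple(p.get("barriers",
                                ((4.0, -0.1, 0.12), (5.0, 0.7, 0.12))))
        return Landscape(kind="downhill_barriers",
                         params={"slope": slope, "intercept": 0.0,
                                 "gaussians": gaussians},
                         domain=domain)
    if archetype == "nonsubstrate_entry_barrier":
        base = make_landscape("substrate_downhill", p)
        height = p.get("entry_barrier_height", 8.0)
        center = p.get("entry_barrier_center", -0.75)
        width = p.get("entry_barrier_width", 0.12)
        gs = tuple(base.params["gaussians"]) + ((height, center, width),)
        return Landscape(kind="entry_barrier",
                         params={**base.params, "gaussians": gs},
                         domain=domain)
    raise ValueError(f"unknown landscape archetype: {archetype!r}")


# ---------------------------------------------------------------------------
# Transport phenotypes

def make_transport_labels() -> pd.DataFrame:
    """Transport outcome for every (molecule, variant) pair.

    IBA is exported by every gate variant except A1357V; CLX only by Wt
    and L704Y; IAA only by L704Y and L704S; indole only by L704Y.
    """
    rows = []
    for mol in MOLECULES:
        for var in VARIANTS:
            if mol == "IBA":
                t = int(var != "A1357V")
            elif mol == "CLX":
                t = int(var in ("Wt", "L704Y"))
            elif mol == "IAA":
                t = int(var in ("L704Y", "L704S"))
            else:  # IND
                t = int(var == "L704Y")
            rows.append((mol, var, t))
    return pd.DataFrame(rows, columns=["molecule", "variant", "transported"])


# ---------------------------------------------------------------------------
# Contact-frequency panels

@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic pulling panel."""

    molecules: Tuple[str, ...] = MOLECULES
    variants: Tuple[str, ...] = VARIANTS
    n_replicates: int = 25
    promote_residues: Tuple[str, ...] = PROMOTE_RESIDUES
    counteract_residues: Tuple[str, ...] = COUNTERACT_RESIDUES
    background_residues: Tuple[str, ...] = BACKGROUND_RESIDUES
    effect_size: float = 0.3
    noise_sd: float = 0.05
    baseline: float = 0.2
    seed: int = 0
    mode: str = "direct"  # or "mechanistic"

    def __post_init__(self):
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must lie in [0, 1)")
        if set(self.promote_residues) & set(self.counteract_residues):
            raise ValueError("promote and counteract residue sets must be disjoint")

    @property
    def residues(self) -> Tuple[str, ...]:
        return self.promote_residues + self.counteract_residues + self.background_residues


def _direct_table(spec: PanelSpec, rng: np.random.Generator,
                  transported: int) -> Tuple[np.ndarray, int]:
    res = spec.residues
    vals = rng.normal(spec.baseline, spec.noise_sd, size=len(res))
    shift = np.zeros(len(res))
    for i, r in enumerate(res):
        if r in spec.promote_residues:
            shift[i] = spec.effect_size if transported else 0.0
        elif r in spec.counteract_residues:
            shift[i] = -0.5 * spec.effect_size if transported else 0.5 * spec.effect_size
    raw = vals + shift
    clipped = np.clip(raw, -1.0, 1.0)
    return clipped, int((raw != clipped).sum())


def _mechanistic_table(spec: PanelSpec, transported: int, seed: int
                       ) -> ContactFrequencyTable:
    land = make_landscape("substrate_downhill" if transported
                          else "nonsubstrate_entry_barrier")
    zones = [ResidueZone(r, ZONE_CENTERS[r]) for r in spec.residues]
    # weak spring + fast center sweep: gate dwell then reflects the
    # entry-escape delay instead of being erased by the moving restraint
    pull = PullConfig(force_constant=1.0, velocity=40.0)  # desk-rescaled
    traj = run_constant_velocity_pull(
        land, pull, LangevinParams(), WallSpec(), zones,
        z_start=-1.0, n_steps=60_000, seed=seed, frame_spacing=1.0)
    return adjusted_contact_frequencies(traj, window=10.0)


def make_pull_panel(spec: PanelSpec | None = None
                    ) -> Tuple[List[ContactFrequencyTable], pd.DataFrame]:
    """Generate the labeled contact-frequency panel.

    direct mode: per (molecule, variant, replicate) the adjusted frequency
    of each residue is a clipped Gaussian around the baseline, shifted by
    +effect_size (promoting residues, transported runs), -effect_size/2
    (counteracting residues, transported runs) or +effect_size/2
    (counteracting residues, non-transported runs).

    mechanistic mode: each simulation is an actual steered pull on the
    matched landscape archetype with the residue zone map, fed through the
    contact statistics.
    """
    spec = spec or PanelSpec()
    labels = make_transport_labels()
    lab = labels.set_index(["molecule", "variant"])["transported"]
    tables: List[ContactFrequencyTable] = []
    n_clipped = 0
    n_total = 0
    base_seed = spec.seed
    idx = 0
    for mol in spec.molecules:
        for var in spec.variants:
            t = int(lab.loc[(mol, var)])
            for rep in range(spec.n_replicates):
                meta = {"molecule": mol, "variant": var, "replicate": rep,
                        "seed": base_seed + idx, "transported": t,
                        "mode": spec.mode,
                        "promote_residues": spec.promote_residues,
                        "counteract_residues": spec.counteract_residues}
                if spec.mode == "direct":
                    rng = np.random.default_rng(base_seed + idx)
                    vals, nc = _direct_table(spec, rng, t)
                    n_clipped += nc
                    n_total += vals.size
                    df = pd.DataFrame({"residue": spec.residues,
                                       "raw_frequency": np.clip(np.abs(vals), 0, 1),
                                       "adjusted_frequency": vals})
                    tables.append(ContactFrequencyTable(table=df, metadata=meta))
                elif spec.mode == "mechanistic":
                    tab = _mechanistic_table(spec, t, base_seed + idx)
                    tab.metadata.update(meta)
                    tables.append(tab)
                else:
                    raise ValueError(f"unknown panel mode: {spec.mode!r}")
                idx += 1
    if n_total and n_clipped / n_total > 0.5:
        warnings.warn("more than half of the panel values were clipped; "
                      "effect_size/noise_sd are probably too large", stacklevel=2)
    mask = labels.molecule.isin(spec.molecules) & labels.variant.isin(spec.variants)
    return tables, labels[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sequence panels

#: round-number per-taxon gate-residue distributions (qualitative shapes:
#: the first gate position of each half is phenylalanine/tyrosine dominated,
#: the second is more spread, with leucine frequent in Brassicaceae)
DEFAULT_GATE_DISTRIBUTIONS: Dict[str, Dict[int, Dict[str, float]]] = {
    "Brassicaceae": {
        703: {"F": 0.60, "Y": 0.20, "L": 0.10, "M": 0.10},
        704: {"F": 0.40, "L": 0.35, "V": 0.20, "I": 0.05},
        1374: {"F": 0.60, "Y": 0.25, "L": 0.15},
        1375: {"F": 0.50, "L": 0.30, "V": 0.20},
    },
    "Fabaceae": {
        703: {"F": 0.50, "Y": 0.30, "L": 0.10, "V": 0.10},
        704: {"F": 0.50, "V": 0.20, "L": 0.20, "I": 0.10},
        1374: {"F": 0.55, "Y": 0.30, "L": 0.15},
        1375: {"F": 0.55, "L": 0.25, "V": 0.20},
    },
    "Solanaceae": {
        703: {"F": 0.55, "Y": 0.25, "L": 0.10, "I": 0.10},
        704: {"F": 0.45, "L": 0.25, "V": 0.20, "M": 0.10},
        1374: {"F": 0.60, "Y": 0.20, "L": 0.20},
        1375: {"F": 0.45, "L": 0.35, "V": 0.20},
    },
}

#: taxon sizes of the screened panels
DEFAULT_TAXON_SIZES = {"Brassicaceae": 598, "Fabaceae": 762, "Solanaceae": 450}

_SCAFFOLD_LENGTH = 1450
_MOTIF_STARTS = (120, 260, 820, 1100)  # 1-based, clear of segments and gates
_SEGMENTS = {(582, 597): "FGMIINMFNGFAEMAM",
             (685, 700): "IANTGGALTLLLVFLL",
             (1250, 1265): "LYAAIIFVGINNCSTV",
             (1356, 1371): "VASIFASAFYGIFNLF"}
_SCAFFOLD_GATES = {703: "F", 704: "L", 1374: "F", 1375: "F"}


@dataclass(frozen=True)
class SequencePanelSpec:
    """Specification of a taxon-structured ABCG-like sequence panel."""

    taxon_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_SIZES))
    gate_distributions: Mapping[str, Mapping[int, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_GATE_DISTRIBUTIONS)
    length_range: Tuple[int, int] = (1000, 1600)
    plant_motifs: bool = True
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not 950 <= lo <= hi <= 1800:
            raise ValueError("length_range must lie within [950, 1800]")
        for taxon, dists in self.gate_distributions.items():
            for pos, d in dists.items():
                if abs(sum(d.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{taxon} distribution at {pos} does not sum to 1")


@dataclass
class SequencePanel:
    """Generated records, per-record truth table and the reference scaffold."""

    records: List[SeqRecord]
    truth: pd.DataFrame
    scaffold: SeqRecord


def make_reference_scaffold(seed: int = 0) -> SeqRecord:
    """AtABCG36-like reference: random background with the printed helix
    segments at 582-597 / 685-700 / 1250-1265 / 1356-1371, the gate
    residues F703/L704/F1374/F1375 and the four PDR motifs planted."""
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list(AMINO_ACIDS), size=_SCAFFOLD_LENGTH)))
    for (a, b), s in _SEGMENTS.items():
        seq[a - 1:b] = list(s)
    for pos, aa in _SCAFFOLD_GATES.items():
        seq[pos - 1] = aa
    for start, motif in zip(_MOTIF_STARTS, PDR_MOTIFS):
        inst = [rng.choice(list(AMINO_ACIDS)) if c == "X" else c for c in motif]
        seq[start - 1:start - 1 + len(inst)] = inst
    return SeqRecord(id="AtABCG36", taxon="Brassicaceae", residues="".join(seq))


def _scaffold_elements(scaffold: str) -> List[Tuple[str, str, dict]]:
    """Ordered (name, subsequence, {gate position: offset}) blocks shared
    between the scaffold and every generated record."""
    blocks = []
    spans = [("M1", _MOTIF_STARTS[0], _MOTIF_STARTS[0] + len(PDR_MOTIFS[0]) - 1, {}),
             ("M2", _MOTIF_STARTS[1], _MOTIF_STARTS[1] + len(PDR_MOTIFS[1]) - 1, {}),
             ("B1", 582, 597, {}),
             ("B2", 685, 712, {703: 18, 704: 19}),
             ("M3", _MOTIF_STARTS[2], _MOTIF_STARTS[2] + len(PDR_MOTIFS[2]) - 1, {}),
             ("M4", _MOTIF_STARTS[3], _MOTIF_STARTS[3] + len(PDR_MOTIFS[3]) - 1, {}),
             ("B3", 1250, 1265, {}),
             ("B4", 1356, 1383, {1374: 18, 1375: 19})]
    for name, a, b, gates in spans:
        blocks.append((name, scaffold[a - 1:b], gates))
    return blocks


def make_sequence_panel(spec: SequencePanelSpec | None = None) -> SequencePanel:
    """Generate the taxon-structured sequence panel with ground truth.

    Each record is a random background sequence carrying copies of the
    scaffold's helix/gate blocks (gate residues redrawn from the taxon's
    distribution) and, when planting is on, the four PDR signature motifs,
    all in scaffold order at randomized offsets. With a nonzero
    ``decoy_fraction`` some records are made to fail the full-size screen
    (one high-specificity motif omitted, or length pushed outside
    [950, 1800]); the truth table records the planted status and reason.
    """
    spec = spec or SequencePanelSpec()
    rng = np.random.default_rng(spec.seed)
    scaffold = make_reference_scaffold(spec.seed)
    blocks = _scaffold_elements(scaffold.residues)
    aa_list = list(AMINO_ACIDS)
    lo, hi = spec.length_range
    # inter-block regions of the scaffold; record backgrounds are mutated,
    # length-adjusted copies so records stay alignable homologs
    bounds = [(120, 125), (260, 264), (582, 597), (685, 712),
              (820, 831), (1100, 1106), (1250, 1265), (1356, 1383)]
    inter = []
    prev = 0
    for a, b in bounds:
        inter.append(scaffold.residues[prev:a - 1])
        prev = b
    inter.append(scaffold.residues[prev:])

    def mutated_background(template: str, target_len: int) -> str:
        chars = [c if rng.random() > 0.65 else str(rng.choice(aa_list))
                 for c in template]
        while len(chars) > target_len:
            del chars[int(rng.integers(0, len(chars)))]
        while len(chars) < target_len:
            chars.insert(int(rng.integers(0, len(chars) + 1)), str(rng.choice(aa_list)))
        return "".join(chars)

    records: List[SeqRecord] = []
    truth_rows = []
    i = 0
    for taxon, n in spec.taxon_sizes.items():
        dists = spec.gate_distributions[taxon]
        for _ in range(n):
            i += 1
            rid = f"seq{i:05d}"
            decoy = rng.random() < spec.decoy_fraction
            reason = ""
            length = int(rng.integers(lo, hi + 1))
            drop_motif = None
            if decoy:
                kind = rng.choice(["motif", "short", "long"])
                if kind == "motif":
                    drop_motif = rng.choice(["M3", "M4"])  # high-specificity
                    reason = ("motif GLDARXAAXVMR" if drop_motif == "M3"
                              else "motif VCTIHQP")
                elif kind == "short":
                    length = 900
                    reason = "length"
                else:
                    length = 1850
                    reason = "length"
            gates = {p: str(rng.choice(list(d.keys()),
                                       p=np.fromiter(d.values(), dtype=float)))
                     for p, d in dists.items()}
            elements = []  # (background template, block)
            tmpl = inter[0]
            for k, (name, sub, goff) in enumerate(blocks):
                if name.startswith("M") and (not spec.plant_motifs or name == drop_motif):
                    tmpl += inter[k + 1]
                    continue
                if goff:
                    sub = list(sub)
                    for pos, off in goff.items():
                        sub[off] = gates[pos]
                    sub = "".join(sub)
                elements.append((tmpl, (name, sub, goff)))
                tmpl = inter[k + 1]
            total = sum(len(b[1]) for _, b in elements)
            free = length - total
            if free < 0:
                raise ValueError("length range below the motif-packing minimum")
            p = np.array([len(t) for t, _ in elements] + [len(tmpl)], dtype=float)
            gap_lens = rng.multinomial(free, p / p.sum())
            parts = []
            gate_positions = {}
            cursor = 0
            for k, (gap_tmpl, (name, sub, goff)) in enumerate(elements):
                bg = mutated_background(gap_tmpl, gap_lens[k])
                parts.append(bg)
                cursor += len(bg)
                for pos, off in goff.items():
                    gate_positions[pos] = cursor + off + 1  # 1-based
                parts.append(sub)
                cursor += len(sub)
            parts.append(mutated_background(tmpl, gap_lens[-1]))
            seq = "".join(parts)
            records.append(SeqRecord(id=rid, taxon=taxon, residues=seq))
            truth_rows.append({
                "id": rid, "taxon": taxon, "full_size": int(not decoy),
                "reason": reason,
                **{f"aa{p}": gates[p] for p in sorted(gates)},
                **{f"pos{p}": gate_positions[p] for p in sorted(gate_positions)},
            })
    truth = pd.DataFrame(truth_rows)
    return SequencePanel(records=records, truth=truth, scaffold=scaffold)
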