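"""Species catalogue and mass-action reaction network for the pYtag model.

The model tracks an RTK (EGFR) whose individual receptors carry three binary
states — ligand-bound, dimerized, and reporter(ZtSH2)-bound — plus the free
soluble ligand and the free cytosolic reporter.  Enumerating every possible
combination of the three per-receptor states yields 16 species:

* ``N1``  free ligand (held constant; ligand is in vast excess to receptor)
* ``N2``  free reporter (tandem SH2, cytosolic)
* ``N3``, ``N4``, and two dissociation intermediates: the four monomer states
* ``N5``  the ligand-free (pre-formed, inactive) receptor dimer
* the remaining dimer states (unordered pairs of per-receptor states)

Binding rules, all mass action:

* ligand associates with any unliganded receptor (monomeric or within a
  dimer) at ``k1`` and dissociates at ``beta * k7``;
* two monomers dimerize at ``k5`` (written so that the homodimerization flux
  of the free monomer is ``k5 * [N3]**2``, which makes the analytic
  pre-stimulus dimer concentration an exact fixed point);
* a dimer dissociates at ``k6`` when it carries no ligand and at
  ``gamma * k3`` when it carries at least one ligand — dimerization and
  autophosphorylation are lumped into a single event, so a ligand-bearing
  dimer is the active, phosphorylated complex;
* the reporter associates at ``k2`` with either receptor tail of a dimer
  carrying >= 1 ligand (trans-autophosphorylation exposes both tails) and
  dissociates at ``k4`` from any reporter-bound receptor.

Reporter-bound species without ligand (e.g. a reporter-bound monomer) are
never produced by association; they occur only transiently when an active
complex loses its ligand or falls apart before the reporter unbinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRecord",
    "SpeciesIndex",
    "Reaction",
    "enumerate_species",
    "build_reactions",
    "reaction_arrays",
    "conserved_totals",
    "species_table",
]

# per-receptor state: (ligand_bound, reporter_bound), each 0 or 1
_MONOMER_STATES = [(0, 0), (1, 0), (0, 1), (1, 1)]

# rate-constant slots (index into the parameter vector k1..k7)
K1, K2, K3, K4, K5, K6, K7 = range(7)


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species catalogue."""

    label: str
    receptor_count: int
    ligand_occupancy: int
    reporter_occupancy: int
    is_dimer: bool
    is_free_ligand: bool
    is_free_reporter: bool
    # per-receptor (ligand, reporter) states; empty for the two free species
    receptor_states: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class SpeciesIndex:
    """Ordered catalogue of the 16 model species (labels ``N1`` .. ``N16``)."""

    entries: tuple[SpeciesRecord, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterable[SpeciesRecord]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> SpeciesRecord:
        return self.entries[i]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    def position(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def free_ligand(self) -> int:
        return next(i for i, e in enumerate(self.entries) if e.is_free_ligand)

    @property
    def free_reporter(self) -> int:
        return next(i for i, e in enumerate(self.entries) if e.is_free_reporter)

    @property
    def receptor_weights(self) -> np.ndarray:
        """Receptor copies per complex; conservation vector for total receptor."""
        return np.array([e.receptor_count for e in self.entries], dtype=float)

    @property
    def reporter_weights(self) -> np.ndarray:
        """Reporter copies per entry, counting the free reporter itself."""
        w = np.array([e.reporter_occupancy for e in self.entries], dtype=float)
        w[self.free_reporter] = 1.0
        return w


def _dimer_key(a: tuple[int, int], b: tuple[int, int]) -> tuple:
    return tuple(sorted((a, b)))


def enumerate_species() -> SpeciesIndex:
    """Build the canonical 16-species index.

    Order: free ligand, free reporter, bare monomer, ligand-bound monomer,
    ligand-free dimer, then the active/partially-occupied dimers, then the
    reporter-carrying dissociation intermediates.
    """
    records: list[SpeciesRecord] = [
        SpeciesRecord("N1", 0, 0, 0, False, True, False),
        SpeciesRecord("N2", 0, 0, 0, False, False, True),
    ]

    def monomer(state: tuple[int, int]) -> tuple:
        lig, rep = state
        return ("m", lig, rep, False, (state,))

    def dimer(a: tuple[int, int], b: tuple[int, int]) -> tuple:
        a, b = _dimer_key(a, b)
        return ("d", a[0] + b[0], a[1] + b[1], True, (a, b))

    # canonical structural order; N3 = bare monomer, N4 = ligand-bound
    # monomer, N5 = ligand-free dimer (the species that exist pre-stimulus
    # are N1..N3 and N5).  N6..N12 are the ligand-bearing dimers in order of
    # increasing occupancy; N13..N16 are reporter-bound, ligand-free
    # dissociation intermediates.
    structural = [
        monomer((0, 0)),                 # N3
        monomer((1, 0)),                 # N4
        dimer((0, 0), (0, 0)),           # N5
        dimer((1, 0), (0, 0)),           # N6  one ligand
        dimer((1, 0), (1, 0)),           # N7  two ligands
        dimer((1, 1), (0, 0)),           # N8  one ligand, reporter on it
        dimer((1, 0), (0, 1)),           # N9  one ligand, reporter on the other tail
        dimer((1, 1), (0, 1)),           # N10 one ligand, two reporters
        dimer((1, 1), (1, 0)),           # N11 two ligands, one reporter
        dimer((1, 1), (1, 1)),           # N12 two ligands, two reporters
        dimer((0, 1), (0, 0)),           # N13 ligand lost, one reporter
        dimer((0, 1), (0, 1)),           # N14 ligand lost, two reporters
        monomer((0, 1)),                 # N15 reporter-bound monomer
        monomer((1, 1)),                 # N16 liganded, reporter-bound monomer
    ]
    for n, (kind, lig, rep, is_dim, states) in enumerate(structural, start=3):
        records.append(
            SpeciesRecord(
                label=f"N{n}",
                receptor_count=2 if is_dim else 1,
                ligand_occupancy=lig,
                reporter_occupancy=rep,
                is_dimer=is_dim,
                is_free_ligand=False,
                is_free_reporter=False,
                receptor_states=states,
            )
        )
    return SpeciesIndex(tuple(records))


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action channel.

    The flux is ``k[rate_index] * multiplier * prod(concentrations of
    reactants)``; the free-ligand concentration enters through
    ``uses_ligand`` (it is clamped, not an integrated state, so it is not a
    ``reactants`` entry).
    """

    name: str
    rate_index: int
    multiplier: float
    uses_ligand: bool
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    kind: str


def _species_maps(index: SpeciesIndex):
    mono = {}
    dim = {}
    for i, e in enumerate(index):
        if e.is_free_ligand or e.is_free_reporter:
            continue
        if e.is_dimer:
            dim[_dimer_key(*e.receptor_states)] = i
        else:
            mono[e.receptor_states[0]] = i
    return mono, dim


def build_reactions(index: SpeciesIndex | None = None) -> list[Reaction]:
    """Generate the declarative reaction list from the binding rules."""
    if index is None:
        index = enumerate_species()
    mono, dim = _species_maps(index)
    z_free = index.free_reporter
    rxns: list[Reaction] = []

    def add(name, rate, mult, uses_l, reac, prod, kind):
        rxns.append(Reaction(name, rate, float(mult), uses_l, tuple(reac), tuple(prod), kind))

    # --- monomer ligand exchange -------------------------------------------
    for (lig, rep), i in mono.items():
        if lig == 0:
            j = mono[(1, rep)]
            add(f"L+{index[i].label}->{index[j].label}", K1, 1, True, [i], [j], "ligand_on")
        else:
            j = mono[(0, rep)]
            add(f"{index[i].label}->{index[j].label}+L", K7, 1, False, [i], [j], "ligand_off")

    # --- dimer ligand exchange (per receptor slot, identical slots merged) --
    for key, i in dim.items():
        for slot in (0, 1):
            a, b = key
            s = key[slot]
            if s[0] == 0:
                new = ((1, s[1]), key[1 - slot])
                j = dim[_dimer_key(*new)]
                _merge_or_add(rxns, add, f"L+{index[i].label}->{index[j].label}",
                              K1, True, (i,), (j,), "ligand_on")
            else:
                new = ((0, s[1]), key[1 - slot])
                j = dim[_dimer_key(*new)]
                _merge_or_add(rxns, add, f"{index[i].label}->{index[j].label}+L",
                              K7, False, (i,), (j,), "ligand_off")

    # --- reporter exchange --------------------------------------------------
    # association only onto dimers that carry >= 1 ligand (the active,
    # phosphorylated complexes); dissociation from any reporter-bound tail.
    for key, i in dim.items():
        total_lig = key[0][0] + key[1][0]
        for slot in (0, 1):
            s = key[slot]
            if s[1] == 0 and total_lig >= 1:
                new = ((s[0], 1), key[1 - slot])
                j = dim[_dimer_key(*new)]
                _merge_or_add(rxns, add, f"Z+{index[i].label}->{index[j].label}",
                              K2, False, (i, z_free), (j,), "reporter_on")
            if s[1] == 1:
                new = ((s[0], 0), key[1 - slot])
                j = dim[_dimer_key(*new)]
                _merge_or_add(rxns, add, f"{index[i].label}->{index[j].label}+Z",
                              K4, False, (i,), (j, z_free), "reporter_off")
    for (lig, rep), i in mono.items():
        if rep == 1:
            j = mono[(lig, 0)]
            add(f"{index[i].label}->{index[j].label}+Z", K4, 1, False, [i], [j, z_free],
                "reporter_off")

    # --- dimerization and dimer dissociation --------------------------------
    # Homodimerization flux is k5*[A]^2 (one dimer formed per collision pair),
    # the convention under which the printed pre-stimulus quadratic is exact;
    # the consistent heterodimerization flux is then 2*k5*[A][B].
    states = list(mono)
    for x in range(len(states)):
        for y in range(x, len(states)):
            a, b = states[x], states[y]
            i, j = mono[a], mono[b]
            d = dim[_dimer_key(a, b)]
            mult = 1 if x == y else 2
            add(f"{index[i].label}+{index[j].label}->{index[d].label}",
                K5, mult, False, [i, j], [d], "dimerize")
    for key, d in dim.items():
        i, j = mono[key[0]], mono[key[1]]
        total_lig = key[0][0] + key[1][0]
        rate = K3 if total_lig >= 1 else K6
        add(f"{index[d].label}->{index[i].label}+{index[j].label}",
            rate, 1, False, [d], [i, j], "undimerize")

    return rxns


def _merge_or_add(rxns, add, name, rate, uses_l, reac, prod, kind):
    """Identical slot transitions on a symmetric dimer merge into mult=2."""
    for n, r in enumerate(rxns):
        if (r.rate_index == rate and r.uses_ligand == uses_l
                and r.reactants == reac and r.products == prod and r.kind == kind):
            rxns[n] = Reaction(r.name, r.rate_index, r.multiplier + 1.0,
                               r.uses_ligand, r.reactants, r.products, r.kind)
            return
    add(name, rate, 1, uses_l, reac, prod, kind)


def reaction_arrays(index: SpeciesIndex | None = None,
                    reactions: list[Reaction] | None = None):
    """Flatten the reaction list into arrays consumable by the kernels.

    Returns ``(rate_index, multiplier, uses_ligand, reactant1, reactant2,
    stoich)`` where ``stoich`` is the dense (n_species x n_reactions) integer
    stoichiometry matrix.  The free-ligand row is zeroed (clamped species).
    """
    if index is None:
        index = enumerate_species()
    if reactions is None:
        reactions = build_reactions(index)
    n_s, n_r = len(index), len(reactions)
    rate_index = np.empty(n_r, dtype=np.int64)
    multiplier = np.empty(n_r, dtype=np.float64)
    uses_ligand = np.zeros(n_r, dtype=np.bool_)
    r1 = np.full(n_r, -1, dtype=np.int64)
    r2 = np.full(n_r, -1, dtype=np.int64)
    stoich = np.zeros((n_s, n_r), dtype=np.float64)
    for j, rx in enumerate(reactions):
        rate_index[j] = rx.rate_index
        multiplier[j] = rx.multiplier
        uses_ligand[j] = rx.uses_ligand
        if len(rx.reactants) >= 1:
            r1[j] = rx.reactants[0]
        if len(rx.reactants) == 2:
            r2[j] = rx.reactants[1]
        for i in rx.reactants:
            stoich[i, j] -= 1.0
        for i in rx.products:
            stoich[i, j] += 1.0
    stoich[index.free_ligand, :] = 0.0  # ligand is clamped
    return rate_index, multiplier, uses_ligand, r1, r2, stoich


def conserved_totals(state: np.ndarray, index: SpeciesIndex | None = None
                     ) -> dict[str, float]:
    """Receptor and reporter totals of a state vector (both conserved).

    ``receptor_total = sum receptor_count * concentration`` and
    ``reporter_total = free reporter + sum reporter_occupancy *
    concentration``.
    """
    if index is None:
        index = enumerate_species()
    state = np.asarray(state, dtype=float)
    return {
        "receptor_total": float(index.receptor_weights @ state),
        "reporter_total": float(index.reporter_weights @ state),
    }


def species_table(index: SpeciesIndex | None = None) -> pd.DataFrame:
    """Species catalogue as a DataFrame (exportable as delimited text)."""
    if index is None:
        index = enumerate_species()
    return pd.DataFrame(
        {
            "label": [e.label for e in index],
            "receptor_count": [e.receptor_count for e in index],
            "ligand_occupancy": [e.ligand_occupancy for e in index],
            "reporter_occupancy": [e.reporter_occupancy for e in index],
            "is_dimer": [e.is_dimer for e in index],
            "is_free_ligand": [e.is_free_ligand for e in index],
            "is_free_reporter": [e.is_free_reporter for e in index],
        }
    )
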