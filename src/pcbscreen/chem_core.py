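"""Elemental-formula arithmetic and the biotransformation rule engine.

This module provides the chemistry backbone of the package: exact
monoisotopic masses, m/z of deprotonated anions (the species observed in
negative-mode electrospray), signed ppm mass errors, and a small rule
engine that expands a parent compound (by default PCB95, C12H5Cl5) into a
suspect list of candidate metabolites by composing biotransformation
steps — aromatic hydroxylation, O-sulfation, ring C-sulfonation, catechol
O-methylation, and reductive dechlorination.

Candidates are identified by elemental composition plus metabolite class;
positional isomers are deliberately not distinguished, since accurate mass
alone cannot separate them.
"""

from __future__ import annotations

import csv
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

# Principal-isotope (monoisotopic) atomic masses, Da.  Pinned so that anion
# m/z values are reproducible to 5 decimal places across environments.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "F": 18.99840316,
    "S": 31.97207117,
    "Cl": 34.96885268,
}

#: Electron rest mass in Da; a singly charged anion carries one extra electron.
ELECTRON_MASS: float = 0.00054858

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping[str, int]):
    """An immutable element -> count map with formula arithmetic.

    Counts are always non-negative; arithmetic that would drive a count
    below zero raises ``ValueError``.  Equality and hashing are count-wise,
    so two formulas with the same composition compare equal regardless of
    construction order.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n > 0:
                clean[sym] = n
        self._counts = dict(sorted(clean.items()))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a plain formula string such as ``"C12H5Cl5"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            sym, digits = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts.get(sym, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, sym) -> bool:
        return sym in self._counts

    # Arithmetic ---------------------------------------------------------
    def add(self, delta: Mapping[str, int]) -> "ElementalFormula":
        """Return a new formula with ``delta`` applied (may be negative)."""
        counts = dict(self._counts)
        for sym, d in delta.items():
            new = counts.get(sym, 0) + int(d)
            if new < 0:
                raise ValueError(
                    f"applying delta would give negative {sym} count on {self.hill()}"
                )
            counts[sym] = new
        return ElementalFormula(counts)

    def remove(self, delta: Mapping[str, int]) -> "ElementalFormula":
        return self.add({sym: -d for sym, d in delta.items()})

    def hill(self) -> str:
        """Hill-notation string: C, H, then the other elements alphabetically."""
        parts = []
        for sym in ("C", "H"):
            n = self._counts.get(sym, 0)
            if n:
                parts.append(f"{sym}{n if n != 1 else ''}")
        for sym in sorted(self._counts):
            if sym in ("C", "H"):
                continue
            n = self._counts[sym]
            parts.append(f"{sym}{n if n != 1 else ''}")
        return "".join(parts)

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Exact monoisotopic mass in Da: sum of principal-isotope masses."""
    total = 0.0
    for sym, n in formula.items():
        try:
            mass = MONOISOTOPIC_MASS[sym]
        except KeyError:
            raise ValueError(f"no tabulated monoisotopic mass for element {sym!r}")
        total += n * mass
    return total


def ion_mz(neutral: Mapping[str, int], charge: int = -1) -> float:
    """m/z of a (de)protonated ion of the neutral formula.

    For negative charge ``-z`` the ion is ``[M - zH]^z-``: z hydrogens are
    removed and z electrons retained, so the electron mass enters with a
    plus sign.  For positive charge the ion is ``[M + zH]^z+``.
    """
    if charge == 0:
        raise ValueError("charge must be nonzero for m/z computation")
    neutral = neutral if isinstance(neutral, ElementalFormula) else ElementalFormula(neutral)
    z = abs(charge)
    if charge < 0:
        if neutral["H"] < z:
            raise ValueError(
                f"{neutral.hill()} lacks {z} hydrogen(s) to remove for deprotonation"
            )
        ion = neutral.remove({"H": z})
        return (monoisotopic_mass(ion) + z * ELECTRON_MASS) / z
    ion = neutral.add({"H": z})
    return (monoisotopic_mass(ion) - z * ELECTRON_MASS) / z


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error, (measured - theoretical)/theoretical x 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class MassError:
    measured_mz: float
    theoretical_mz: float

    @property
    def delta_ppm(self) -> float:
        return ppm_error(self.measured_mz, self.theoretical_mz)


@dataclass(frozen=True)
class IonSpecies:
    """A charged species derived from a neutral formula by (de)protonation."""

    neutral: ElementalFormula
    charge: int = -1

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("charge must be nonzero")

    @property
    def ion_formula(self) -> ElementalFormula:
        z = abs(self.charge)
        if self.charge < 0:
            return self.neutral.remove({"H": z})
        return self.neutral.add({"H": z})

    @property
    def mz(self) -> float:
        return ion_mz(self.neutral, self.charge)


# ---------------------------------------------------------------------------
# Biotransformation rules
# ---------------------------------------------------------------------------

Constraint = Callable[[ElementalFormula, Mapping[str, int]], bool]


@dataclass(frozen=True)
class BiotransformationRule:
    """One metabolic step expressed as an element-count delta.

    ``constraint`` receives the current formula and a map of how many times
    each rule has already been applied along the chain; it must return True
    for the rule to be applicable.  ``max_applications`` bounds how many
    times this rule may occur in a single chain.
    """

    name: str
    delta: Mapping[str, int]
    max_applications: int = 1
    constraint: Constraint | None = None
    description: str = ""

    def applicable(self, formula: ElementalFormula, applied: Mapping[str, int]) -> bool:
        if applied.get(self.name, 0) >= self.max_applications:
            return False
        if self.constraint is not None and not self.constraint(formula, applied):
            return False
        try:
            formula.add(self.delta)
        except ValueError:
            return False
        return True


def _n_conjugations(applied: Mapping[str, int]) -> int:
    return sum(applied.get(r, 0) for r in ("SULF-O", "SULFON-C", "METH"))


def _free_hydroxyls(applied: Mapping[str, int]) -> int:
    # Each hydroxylation adds one OH; O-sulfation and O-methylation each
    # occupy one.  Formula counts alone cannot see this, so it is tracked
    # through rule provenance.
    return applied.get("OX", 0) - applied.get("SULF-O", 0) - applied.get("METH", 0)


def default_rules() -> dict[str, BiotransformationRule]:
    """The rule set used for PCB suspect-list generation.

    OX       aromatic hydroxylation (+O), up to three times;
    SULF-O   sulfation of a phenolic hydroxyl (+SO3), one conjugation per chain;
    SULFON-C ring C-sulfonation of the parent (+SO3, mercapturic-acid route);
    METH     catechol O-methylation (+CH2), requires two prior hydroxylations;
    DECHLOR  reductive dechlorination (-Cl +H), up to two successive losses.
    """
    return {
        "OX": BiotransformationRule(
            "OX", {"O": 1}, max_applications=3,
            constraint=lambda f, a: f["H"] >= 1,
            description="cytochrome P450 aromatic hydroxylation",
        ),
        "SULF-O": BiotransformationRule(
            "SULF-O", {"S": 1, "O": 3}, max_applications=1,
            constraint=lambda f, a: _free_hydroxyls(a) >= 1 and _n_conjugations(a) == 0,
            description="sulfotransferase O-sulfation of a phenol",
        ),
        "SULFON-C": BiotransformationRule(
            "SULFON-C", {"S": 1, "O": 3}, max_applications=1,
            constraint=lambda f, a: sum(a.values()) == 0,
            description="ring sulfonation of the parent (mercapturic acid pathway)",
        ),
        "METH": BiotransformationRule(
            "METH", {"C": 1, "H": 2}, max_applications=1,
            constraint=lambda f, a: a.get("OX", 0) >= 2 and _n_conjugations(a) == 0,
            description="catechol-O-methyltransferase methylation (needs a diol)",
        ),
        "DECHLOR": BiotransformationRule(
            "DECHLOR", {"Cl": -1, "H": 1}, max_applications=2,
            constraint=lambda f, a: f["Cl"] >= 1,
            description="enhanced reductive dechlorination",
        ),
    }


def apply_rule(
    formula: ElementalFormula,
    rule: BiotransformationRule,
    applied: Mapping[str, int] | None = None,
) -> ElementalFormula:
    """Apply one rule to a formula, enforcing its constraint and cap."""
    applied = dict(applied or {})
    if applied.get(rule.name, 0) >= rule.max_applications:
        raise ValueError(
            f"rule {rule.name} already applied {applied[rule.name]} time(s), "
            f"max is {rule.max_applications} (formula {formula.hill()})"
        )
    if rule.constraint is not None and not rule.constraint(formula, applied):
        raise ValueError(f"constraint of rule {rule.name} not met on {formula.hill()}")
    try:
        return formula.add(rule.delta)
    except ValueError as exc:
        raise ValueError(f"rule {rule.name} on {formula.hill()}: {exc}") from exc


# Metabolite-class labels keyed by applied-rule counts (OX, SULF-O,
# SULFON-C, METH, DECHLOR).  These are the eight classes a pentachloro-
# biphenyl suspect screen distinguishes by composition.
_CLASS_BY_COUNTS: dict[tuple[int, int, int, int, int], tuple[str, str]] = {
    (0, 0, 0, 0, 0): ("parent", "PCB95"),
    (1, 0, 0, 0, 0): ("1.1", "OH-PCB95"),
    (1, 1, 0, 0, 0): ("1.2", "PCB95 sulfate"),
    (2, 1, 0, 0, 0): ("2", "OH-PCB95 sulfate"),
    (2, 0, 0, 1, 0): ("3", "MeO-OH-PCB95"),
    (3, 0, 0, 1, 0): ("4", "MeO-diOH-PCB95"),
    (0, 0, 1, 0, 0): ("5", "PCB95 sulfonate"),
    (1, 0, 0, 0, 2): ("6", "OH-tri-CB"),
    (1, 0, 0, 0, 1): ("7", "OH-tetra-CB"),
    (2, 0, 0, 0, 2): ("8", "diOH-tri-CB"),
}

_RULE_ORDER = ("OX", "SULF-O", "SULFON-C", "METH", "DECHLOR")


@dataclass(frozen=True)
class SuspectCandidate:
    """A suspect-list entry: one metabolite class as a formula + anion."""

    class_id: str
    name: str
    neutral: ElementalFormula
    ion: IonSpecies
    theoretical_mz: float
    expected_losses: tuple[tuple[str, float], ...]
    provenance: tuple[str, ...]

    @property
    def key(self) -> tuple[str, str]:
        return (self.class_id, self.neutral.hill())


def expected_losses(provenance: Iterable[str]) -> tuple[tuple[str, float], ...]:
    """Diagnostic neutral losses implied by a candidate's rule provenance.

    Methoxylated candidates lose a methyl radical; O-sulfates lose SO3;
    other phenolic, chlorine-bearing candidates lose HCl.  Ring sulfonates
    have no facile loss (the C-S bond does not fragment under these
    conditions).  Loss masses come from the same atomic-mass table as the
    precursor m/z values.
    """
    counts = {name: 0 for name in _RULE_ORDER}
    for r in provenance:
        counts[r] = counts.get(r, 0) + 1
    m = MONOISOTOPIC_MASS
    if counts["METH"] >= 1:
        return (("CH3", m["C"] + 3 * m["H"]),)
    if counts["SULF-O"] >= 1:
        return (("SO3", m["S"] + 3 * m["O"]),)
    if counts["SULFON-C"] >= 1:
        return ()
    if counts["OX"] >= 1:
        return (("HCl", m["H"] + m["Cl"]),)
    return ()


PCB95 = ElementalFormula.parse("C12H5Cl5")


def enumerate_suspects(
    parent: ElementalFormula = PCB95,
    rules: Mapping[str, BiotransformationRule] | None = None,
    max_depth: int = 4,
    charge: int = -1,
    include_parent: bool = True,
    classes_only: bool = False,
) -> list[SuspectCandidate]:
    """Breadth-first closure of rule applications from a parent compound.

    Each reachable state is a formula plus a multiset of applied rules;
    states that yield the same (formula, class) pair are deduplicated, so
    the order in which commuting rules fire does not affect the output.
    Candidates are labeled with a canonical provenance (rules in a fixed
    order) and returned sorted by class id then formula.
    """
    if rules is None:
        rules = default_rules()
    start_counts = tuple(0 for _ in _RULE_ORDER)
    seen: set[tuple[ElementalFormula, tuple[int, ...]]] = set()
    queue: deque[tuple[ElementalFormula, dict[str, int], int]] = deque()
    queue.append((parent, {}, 0))
    seen.add((parent, start_counts))
    states: list[tuple[ElementalFormula, dict[str, int]]] = [(parent, {})]

    while queue:
        formula, applied, depth = queue.popleft()
        if depth >= max_depth:
            continue
        for name in _RULE_ORDER:
            rule = rules.get(name)
            if rule is None or not rule.applicable(formula, applied):
                continue
            nxt = formula.add(rule.delta)
            nxt_applied = dict(applied)
            nxt_applied[name] = nxt_applied.get(name, 0) + 1
            key = (nxt, tuple(nxt_applied.get(r, 0) for r in _RULE_ORDER))
            if key in seen:
                continue
            seen.add(key)
            states.append((nxt, nxt_applied))
            queue.append((nxt, nxt_applied, depth + 1))

    out: dict[tuple[str, str], SuspectCandidate] = {}
    for formula, applied in states:
        counts = tuple(applied.get(r, 0) for r in _RULE_ORDER)
        class_id, name = _CLASS_BY_COUNTS.get(
            counts, (None, None)
        )
        if class_id == "parent" and not include_parent:
            continue
        if class_id is None:
            if classes_only:
                continue
            tag = "+".join(
                f"{r}x{c}" if c > 1 else r
                for r, c in zip(_RULE_ORDER, counts) if c
            )
            class_id = f"other:{tag}"
            name = tag
        provenance = tuple(
            r for r, c in zip(_RULE_ORDER, counts) for _ in range(c)
        )
        ion = IonSpecies(formula, charge)
        cand = SuspectCandidate(
            class_id=class_id,
            name=name,
            neutral=formula,
            ion=ion,
            theoretical_mz=ion.mz,
            expected_losses=expected_losses(provenance),
            provenance=provenance,
        )
        out.setdefault(cand.key, cand)

    def sort_key(c: SuspectCandidate):
        try:
            major = (0, float(c.class_id))
        except ValueError:
            major = (1, 0.0) if c.class_id == "parent" else (2, 0.0)
        return (*major, c.theoretical_mz)

    return sorted(out.values(), key=sort_key)


# ---------------------------------------------------------------------------
# Suspect-list CSV round trip
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "class_id", "name", "neutral_formula", "ion_formula",
    "theoretical_mz", "expected_losses", "provenance",
]


def write_suspects_csv(candidates: Sequence[SuspectCandidate], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for c in candidates:
            writer.writerow({
                "class_id": c.class_id,
                "name": c.name,
                "neutral_formula": c.neutral.hill(),
                "ion_formula": c.ion.ion_formula.hill(),
                "theoretical_mz": f"{c.theoretical_mz:.5f}",
                "expected_losses": ";".join(label for label, _ in c.expected_losses),
                "provenance": ";".join(c.provenance),
            })


def read_suspects_csv(path, charge: int = -1) -> list[SuspectCandidate]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            neutral = ElementalFormula.parse(row["neutral_formula"])
            provenance = tuple(p for p in row["provenance"].split(";") if p)
            ion = IonSpecies(neutral, charge)
            out.append(SuspectCandidate(
                class_id=row["class_id"],
                name=row["name"],
                neutral=neutral,
                ion=ion,
                theoretical_mz=ion.mz,
                expected_losses=expected_losses(provenance),
                provenance=provenance,
            ))
    return out
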