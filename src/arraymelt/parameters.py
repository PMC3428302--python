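"""Free-energy parameter sets for microarray duplex stability calculations.

A duplex context (a nearest-neighbor stack, a mismatch triplet, a bulge
triplet, or a tandem-mismatch quadruplet) is written as two aligned strands:
the *top* strand 5'->3' (by convention the probe) and the *bottom* strand
written 3'->5' so that ``bottom[i]`` is the base physically facing
``top[i]``.  Reading the same physical duplex from the other strand gives the
strand-reversed context; free energies are invariant under that reversal, so
tables are keyed by a canonical representative (the lexicographically smaller
of the two readings).

The shipped default table (``data/microarray_params_synthetic.toml``) is a
synthetic calibration: a parameter set constructed to live on the scale of
microarray-derived rules (weak nearest-neighbor stacks around -0.4 kcal/mol,
mismatch internal loops between roughly -0.1 and +1.8 kcal/mol), not a fit
to any particular platform's data.  It is built deterministically by
:func:`build_synthetic_params`.
"""

from __future__ import annotations

import hashlib
import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import product
from typing import Mapping

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: kcal/(mol K); fixed by convention for all shipped parameter sets.
GAS_CONSTANT = 0.00199

#: Default hybridization temperature (42 C) in kelvin.
DEFAULT_TEMPERATURE = 315.15

#: Initiation free-energy penalty, kcal/mol.  Held fixed because only the
#: product exp(-dG_init/RT) * {P}_o is identifiable from melting data; the
#: effective probe concentration is the member of the pair allowed to vary.
DEFAULT_DG_INIT = 1.96


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the ACGT alphabet."""


class ParameterTableError(KeyError):
    """A free-energy table is missing a required context key."""


class InvalidInputError(ValueError):
    """A context was passed to an operation it is not valid for."""


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def check_sequence(seq: str) -> str:
    seq = seq.upper()
    for ch in seq:
        if ch not in COMPLEMENT:
            raise InvalidSequenceError(f"non-ACGT character {ch!r} in sequence")
    return seq


def complement(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise InvalidSequenceError(f"non-ACGT base {base!r}") from None


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(check_sequence(seq)))


def is_watson_crick(top: str, bottom: str) -> bool:
    return COMPLEMENT.get(top) == bottom


# ---------------------------------------------------------------------------
# canonical context keys
# ---------------------------------------------------------------------------

def context_key(top: str, bottom: str) -> str:
    """Key string for an aligned duplex context (bottom written 3'->5')."""
    return f"{top}/{bottom}"


def reverse_context(top: str, bottom: str) -> tuple[str, str]:
    """The same physical duplex read from the other strand."""
    return bottom[::-1], top[::-1]


def canonical_context(top: str, bottom: str) -> str:
    """Canonical key: the smaller of the two strand readings."""
    if len(top) != len(bottom):
        raise InvalidInputError("aligned context strands must have equal length")
    a = context_key(top, bottom)
    b = context_key(*reverse_context(top, bottom))
    return min(a, b)


def canonical_stack(dimer: str) -> str:
    """Canonical key of a Watson-Crick nearest-neighbor stack.

    ``dimer`` is the two adjacent top-strand bases read 5'->3'; the bottom
    strand is their complement.
    """
    dimer = check_sequence(dimer)
    if len(dimer) != 2:
        raise InvalidInputError("a nearest-neighbor stack is two bases")
    bottom = complement(dimer[0]) + complement(dimer[1])
    return canonical_context(dimer, bottom)


def canonical_mismatch_triplet(top: str, bottom: str) -> str:
    """Canonical key of a single-mismatch triplet.

    The middle pair must be non-Watson-Crick; the flanks must be
    Watson-Crick closing pairs.
    """
    top, bottom = check_sequence(top), check_sequence(bottom)
    if len(top) != 3 or len(bottom) != 3:
        raise InvalidInputError("a mismatch triplet has three aligned pairs")
    if not (is_watson_crick(top[0], bottom[0]) and is_watson_crick(top[2], bottom[2])):
        raise InvalidInputError("triplet flanks must be Watson-Crick closing pairs")
    if is_watson_crick(top[1], bottom[1]):
        raise InvalidInputError("central pair of a mismatch triplet must not be Watson-Crick")
    return canonical_context(top, bottom)


def bulge_key(flank5: str, base: str, flank3: str) -> str:
    """Key of a single-base bulge context.

    Read along the strand that carries the unpaired base, 5'->3': the base of
    that strand in the 5' closing pair, the bulged base, and the base of the
    same strand in the 3' closing pair.  This reading does not change when the
    duplex is viewed from the other strand, so the key is trivially canonical
    and the table carries all 4 x 16 = 64 contexts.
    """
    for b in (flank5, base, flank3):
        if b not in COMPLEMENT:
            raise InvalidSequenceError(f"non-ACGT base {b!r}")
    return f"{flank5}.{base}.{flank3}"


def mismatch_class(probe_base: str, target_base: str) -> str:
    """Stability class of a mismatched pair: GG, GA, GT, or other.

    Strand-symmetric: classification depends only on the unordered pair of
    bases, so G.A and A.G fall in the same class.
    """
    pair = "".join(sorted((probe_base, target_base)))
    if pair == "GG":
        return "GG"
    if pair == "AG":
        return "GA"
    if pair == "GT":
        return "GT"
    return "other"


def closing_class(top: str, bottom: str) -> str:
    """AT or GC class of a Watson-Crick closing pair."""
    if not is_watson_crick(top, bottom):
        raise InvalidInputError(f"{top}.{bottom} is not a Watson-Crick pair")
    return "GC" if top in "GC" else "AT"


def tandem_score_key(closing: str, mm: str) -> str:
    return f"{closing}:{mm}"


# ---------------------------------------------------------------------------
# exhaustive context enumeration
# ---------------------------------------------------------------------------

def enumerate_stacks() -> set[str]:
    """All canonical Watson-Crick nearest-neighbor stacks (10 classes)."""
    return {canonical_stack(a + b) for a, b in product(BASES, repeat=2)}


def enumerate_mismatch_triplets() -> set[str]:
    """All canonical single-mismatch triplets (104 classes).

    192 ordered contexts (4 left closing pairs x 12 mismatched pairs x 4
    right closing pairs) merge to (192 - 16)/2 + 16 = 104 classes under
    strand reversal.
    """
    keys = set()
    for x1, x2, x3, y2 in product(BASES, repeat=4):
        if is_watson_crick(x2, y2):
            continue
        top = x1 + x2 + x3
        bottom = complement(x1) + y2 + complement(x3)
        keys.add(canonical_mismatch_triplet(top, bottom))
    return keys


def enumerate_bulge_contexts() -> set[str]:
    """All single-base bulge contexts (4 bases x 16 flank combinations = 64)."""
    return {bulge_key(a, b, c) for a, b, c in product(BASES, repeat=3)}


def enumerate_tandem_score_keys() -> set[str]:
    """The 8 half-quadruplet rule cells: closing class x mismatch class."""
    return {
        tandem_score_key(c, m)
        for c in ("AT", "GC")
        for m in ("GG", "GA", "GT", "other")
    }


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermoParameterSet:
    """All constants needed to score a probe/target duplex and melt it.

    Free energies are kcal/mol at the set's hybridization temperature.
    ``single_mm_loops`` holds microarray internal-loop values for the 104
    canonical mismatch triplets; ``single_mm_loops_sln`` the corresponding
    in-solution values used by the linear-mapping mode together with
    ``sm_linear`` = (alpha, beta).  Bulge loops are carried on the solution
    scale (``bulge_loops_sln``, 64 contexts) and mapped to the array by the
    slope ``bulge_alpha``.  ``tandem_scores`` are the 8 half-quadruplet rule
    scores; ``tandem_linear`` the linear alternative for supplied solution
    quadruplet values.  ``extended_rules`` may carry explicit penalties for
    conformations outside the derived tables; when absent, a conservative
    fallback is computed from covered analogs sharing the closing pairs.
    """

    nn_free_energies: Mapping[str, float]
    dg_init: float
    single_mm_loops: Mapping[str, float]
    bulge_alpha: float
    bulge_loops_sln: Mapping[str, float]
    tandem_scores: Mapping[str, float]
    sm_linear: tuple[float, float]
    tandem_linear: tuple[float, float]
    m_value: float
    log10_effective_probe_conc: float
    single_mm_loops_sln: Mapping[str, float] | None = None
    extended_rules: Mapping[str, float] | None = None
    gas_constant: float = GAS_CONSTANT
    temperature: float = DEFAULT_TEMPERATURE
    name: str = "unnamed"

    @property
    def effective_probe_conc(self) -> float:
        """{P}_o in molar units."""
        return 10.0 ** self.log10_effective_probe_conc

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    @property
    def init_conc_product(self) -> float:
        """The identifiable constant exp(-dG_init/RT) * {P}_o."""
        return math.exp(-self.dg_init / self.rt) * self.effective_probe_conc

    def with_globals(self, m_value: float | None = None,
                     log10_po: float | None = None) -> "ThermoParameterSet":
        """Copy with replaced global fit parameters."""
        kwargs = {}
        if m_value is not None:
            kwargs["m_value"] = m_value
        if log10_po is not None:
            kwargs["log10_effective_probe_conc"] = log10_po
        return replace(self, **kwargs)

    def nn_stack(self, dimer: str) -> float:
        key = canonical_stack(dimer)
        try:
            return self.nn_free_energies[key]
        except KeyError:
            raise ParameterTableError(f"missing nearest-neighbor entry {key}") from None

    def mismatch_loop(self, top: str, bottom: str) -> float:
        key = canonical_mismatch_triplet(top, bottom)
        try:
            return self.single_mm_loops[key]
        except KeyError:
            raise ParameterTableError(f"missing mismatch loop entry {key}") from None

    def mismatch_loop_sln(self, top: str, bottom: str) -> float:
        if self.single_mm_loops_sln is None:
            raise ParameterTableError("no solution mismatch-loop table attached")
        key = canonical_mismatch_triplet(top, bottom)
        try:
            return self.single_mm_loops_sln[key]
        except KeyError:
            raise ParameterTableError(f"missing solution loop entry {key}") from None

    def bulge_loop_sln(self, flank5: str, base: str, flank3: str) -> float:
        key = bulge_key(flank5, base, flank3)
        try:
            return self.bulge_loops_sln[key]
        except KeyError:
            raise ParameterTableError(f"missing bulge loop entry {key}") from None

    def tandem_score(self, closing: str, mm: str) -> float:
        key = tandem_score_key(closing, mm)
        try:
            return self.tandem_scores[key]
        except KeyError:
            raise ParameterTableError(f"missing tandem rule {key}") from None

    def validate(self) -> None:
        """Check completeness and canonicality of all tables."""
        if self.m_value <= 0:
            raise InvalidInputError("m_value must be positive")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be positive")
        nn_expected = enumerate_stacks()
        if set(self.nn_free_energies) != nn_expected:
            raise ParameterTableError(
                "nearest-neighbor table must have exactly the 10 canonical stacks; "
                f"got {len(self.nn_free_energies)} keys"
            )
        mm_expected = enumerate_mismatch_triplets()
        if set(self.single_mm_loops) != mm_expected:
            raise ParameterTableError(
                "single-mismatch table must have exactly the 104 canonical triplets; "
                f"got {len(self.single_mm_loops)} keys"
            )
        if set(self.bulge_loops_sln) != enumerate_bulge_contexts():
            raise ParameterTableError(
                "bulge table must have exactly the 64 contexts; "
                f"got {len(self.bulge_loops_sln)} keys"
            )
        if set(self.tandem_scores) != enumerate_tandem_score_keys():
            raise ParameterTableError(
                "tandem rule table must have exactly the 8 class cells; "
                f"got {len(self.tandem_scores)} keys"
            )
        if self.single_mm_loops_sln is not None and (
            set(self.single_mm_loops_sln) != mm_expected
        ):
            raise ParameterTableError("solution mismatch table keys are not canonical")

    # -- serialization ------------------------------------------------------

    def to_toml(self) -> str:
        def fmt_table(name: str, table: Mapping[str, float]) -> str:
            lines = [f"[{name}]"]
            for k in sorted(table):
                lines.append(f'"{k}" = {table[k]:.4f}')
            return "\n".join(lines)

        parts = [
            "[global]",
            f'name = "{self.name}"',
            f"m_value = {self.m_value}",
            f"log10_effective_probe_conc = {self.log10_effective_probe_conc}",
            f"dg_init = {self.dg_init}",
            f"gas_constant = {self.gas_constant}",
            f"temperature = {self.temperature}",
            f"bulge_alpha = {self.bulge_alpha}",
            f"sm_linear = [{self.sm_linear[0]}, {self.sm_linear[1]}]",
            f"tandem_linear = [{self.tandem_linear[0]}, {self.tandem_linear[1]}]",
            "",
            fmt_table("nearest_neighbors", self.nn_free_energies),
            "",
            fmt_table("single_mismatch_loops", self.single_mm_loops),
            "",
            fmt_table("bulge", self.bulge_loops_sln),
            "",
            fmt_table("tandem", self.tandem_scores),
        ]
        if self.single_mm_loops_sln is not None:
            parts += ["", fmt_table("single_mismatch_loops_sln", self.single_mm_loops_sln)]
        if self.extended_rules is not None:
            parts += ["", fmt_table("extended", self.extended_rules)]
        return "\n".join(parts) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "ThermoParameterSet":
        doc = tomllib.loads(text)
        g = doc["global"]
        ps = cls(
            nn_free_energies=dict(doc["nearest_neighbors"]),
            dg_init=float(g["dg_init"]),
            single_mm_loops=dict(doc["single_mismatch_loops"]),
            bulge_alpha=float(g["bulge_alpha"]),
            bulge_loops_sln=dict(doc["bulge"]),
            tandem_scores=dict(doc["tandem"]),
            sm_linear=tuple(g["sm_linear"]),
            tandem_linear=tuple(g["tandem_linear"]),
            m_value=float(g["m_value"]),
            log10_effective_probe_conc=float(g["log10_effective_probe_conc"]),
            single_mm_loops_sln=dict(doc["single_mismatch_loops_sln"])
            if "single_mismatch_loops_sln" in doc else None,
            extended_rules=dict(doc["extended"]) if "extended" in doc else None,
            gas_constant=float(g.get("gas_constant", GAS_CONSTANT)),
            temperature=float(g.get("temperature", DEFAULT_TEMPERATURE)),
            name=g.get("name", "unnamed"),
        )
        ps.validate()
        return ps

    @classmethod
    def from_file(cls, path) -> "ThermoParameterSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_toml(fh.read())

    def table_hash(self) -> str:
        """Short content hash identifying the parameter set in outputs."""
        cached = getattr(self, "_table_hash", None)
        if cached is None:
            cached = hashlib.sha256(self.to_toml().encode()).hexdigest()[:12]
            object.__setattr__(self, "_table_hash", cached)
        return cached


# ---------------------------------------------------------------------------
# synthetic default calibration
# ---------------------------------------------------------------------------

# Unified in-solution DNA/DNA nearest-neighbor free energies (37 C scale),
# kcal/mol, keyed canonically; used only to shape the synthetic array table
# and as the solution-scale side of the linear-mapping modes.
SOLUTION_NN = {
    "AA/TT": -1.00,
    "AT/TA": -0.88,
    "TA/AT": -0.58,
    "CA/GT": -1.45,
    "AC/TG": -1.44,
    "AG/TC": -1.28,
    "GA/CT": -1.30,
    "CG/GC": -2.17,
    "GC/CG": -2.24,
    "CC/GG": -1.84,
}

_MM_BASE_PENALTY = {
    "GG": 0.10, "GT": 0.30, "AG": 0.45,
    "AA": 0.90, "TT": 1.00, "CT": 1.20, "AC": 1.30, "CC": 1.50,
}


def _jitter(key: str, scale: float) -> float:
    """Deterministic pseudo-random perturbation in [-scale, scale]."""
    h = int(hashlib.md5(key.encode()).hexdigest(), 16)
    return ((h % 100001) / 100000.0 - 0.5) * 2.0 * scale


def _pair_code(a: str, b: str) -> str:
    return "".join(sorted((a, b)))


def build_synthetic_params() -> ThermoParameterSet:
    """Construct the shipped synthetic microarray calibration.

    Deterministic (no RNG state): array nearest-neighbor stacks are a damped
    linear image of the solution scale (mean about -0.40 kcal/mol, so a
    22-mer melts near 20% formamide under the default globals); mismatch
    loops combine a mismatch-class penalty, closing-pair adjustments, and a
    key-hashed jitter; bulge loops sit on the solution scale around
    +3.6 kcal/mol and reach the array through the 0.238 slope; tandem rules
    score each half-quadruplet by closing-pair and mismatch class.
    """
    nn = {k: round(0.25 * v - 0.046, 4) for k, v in SOLUTION_NN.items()}

    sm_alpha, sm_beta = 0.354, 0.487
    mm_loops: dict[str, float] = {}
    mm_loops_sln: dict[str, float] = {}
    for key in sorted(enumerate_mismatch_triplets()):
        top, bottom = key.split("/")
        penalty = _MM_BASE_PENALTY[_pair_code(top[1], bottom[1])]
        for side in (0, 2):
            penalty += -0.20 if closing_class(top[side], bottom[side]) == "GC" else 0.10
        value = round(penalty + _jitter(key, 0.15), 4)
        mm_loops[key] = value
        # solution-scale counterpart consistent with the linear mapping
        mm_loops_sln[key] = round((value - sm_beta) / sm_alpha, 4)

    bulge_base = {"A": 0.00, "C": 0.10, "G": -0.10, "T": 0.05}
    bulges: dict[str, float] = {}
    for key in sorted(enumerate_bulge_contexts()):
        f5, b, f3 = key.split(".")
        value = 3.6 + bulge_base[b]
        for flank in (f5, f3):
            value += -0.15 if flank in "GC" else 0.05
        bulges[key] = round(value + _jitter(key, 0.20), 4)

    tandem = {
        "GC:GG": 0.05, "GC:GT": 0.15, "GC:GA": 0.25, "GC:other": 0.70,
        "AT:GG": 0.35, "AT:GT": 0.45, "AT:GA": 0.55, "AT:other": 1.00,
    }

    ps = ThermoParameterSet(
        nn_free_energies=nn,
        dg_init=DEFAULT_DG_INIT,
        single_mm_loops=mm_loops,
        single_mm_loops_sln=mm_loops_sln,
        bulge_alpha=0.238,
        bulge_loops_sln=bulges,
        tandem_scores=tandem,
        sm_linear=(sm_alpha, sm_beta),
        tandem_linear=(0.198, 1.167),
        m_value=0.173,
        log10_effective_probe_conc=-2.0,
        name="microarray-synthetic-v1",
    )
    ps.validate()
    return ps


_DEFAULT_CACHE: ThermoParameterSet | None = None


def default_params() -> ThermoParameterSet:
    """The shipped synthetic microarray parameter set (loaded from data)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = (
            resources.files("arraymelt")
            .joinpath("data/microarray_params_synthetic.toml")
            .read_text(encoding="utf-8")
        )
        _DEFAULT_CACHE = ThermoParameterSet.from_toml(text)
    return _DEFAULT_CACHE
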