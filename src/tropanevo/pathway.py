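"""The hyoscyamine/scopolamine (HS) biosynthetic pathway model.

Twelve enzymes convert putrescine (compound 1) through a series of
intermediates to scopolamine (compound 14).  The enzyme list is split into
three segments: tropane-ring formation (PMT, MPO, PYKS, CYP82M3),
phenyllactylglucose (PLA-glucoside) biosynthesis (ArAT4, PPAR, UGT1), and the
terminal medicinal segment (TRI, LS, CYP80F1, HDH, H6H) that is exclusive to
HS production.  A species is called an HS producer when every non-dispensable
enzyme is present in an intact, functional copy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

VALID_STATES = ("intact", "pseudogene", "absent")
SEGMENTS = ("tropane-ring", "PLA-glucoside", "medicinal")


class PathwayError(ValueError):
    """Malformed pathway definition or inconsistent model."""


@dataclass(frozen=True)
class PathwayStep:
    """One enzymatic step: enzyme converting substrate compound to product."""

    index: int
    enzyme_symbol: str
    substrate_compound: int
    product_compound: int
    segment: str

    def __post_init__(self):
        if not 1 <= self.index <= 12:
            raise PathwayError(f"step index {self.index} outside 1-12")
        for c in (self.substrate_compound, self.product_compound):
            if not 1 <= c <= 14:
                raise PathwayError(f"compound id {c} outside 1-14")
        if self.segment not in SEGMENTS:
            raise PathwayError(f"unknown segment {self.segment!r}")


@dataclass
class PathwayModel:
    steps: list[PathwayStep]
    dispensable_enzymes: set[str] = field(default_factory=set)

    def __post_init__(self):
        if len(self.steps) != 12:
            raise PathwayError(f"pathway must have 12 steps, got {len(self.steps)}")
        if sorted(s.index for s in self.steps) != list(range(1, 13)):
            raise PathwayError("step indices 1-12 must each occur exactly once")
        self.steps = sorted(self.steps, key=lambda s: s.index)
        # Within each segment, products chain into the next step's substrate.
        by_seg: dict[str, list[PathwayStep]] = {}
        for s in self.steps:
            by_seg.setdefault(s.segment, []).append(s)
        for seg, steps in by_seg.items():
            for a, b in zip(steps, steps[1:]):
                if a.product_compound != b.substrate_compound:
                    raise PathwayError(
                        f"segment {seg!r} not a substrate->product chain at "
                        f"{a.enzyme_symbol}->{b.enzyme_symbol}"
                    )

    @property
    def enzymes(self) -> list[str]:
        return [s.enzyme_symbol for s in self.steps]

    def step(self, enzyme_symbol: str) -> PathwayStep:
        for s in self.steps:
            if s.enzyme_symbol == enzyme_symbol:
                return s
        raise PathwayError(f"enzyme {enzyme_symbol!r} not in pathway")


def load_pathway(path: str | Path, dispensable_enzymes: set[str] | None = None) -> PathwayModel:
    """Read a pathway definition TSV (index, enzyme, substrate, product, segment)."""
    steps = []
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise PathwayError(f"cannot read pathway file {path}: {exc}") from exc
    header = lines[0].rstrip("\n").split("\t") if lines else []
    if header[:5] != ["index", "enzyme", "substrate", "product", "segment"]:
        raise PathwayError(f"bad pathway header in {path}: {header}")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != 5:
            raise PathwayError(f"bad pathway row: {ln!r}")
        try:
            steps.append(
                PathwayStep(
                    index=int(fields[0]),
                    enzyme_symbol=fields[1],
                    substrate_compound=int(fields[2]),
                    product_compound=int(fields[3]),
                    segment=fields[4],
                )
            )
        except ValueError as exc:
            raise PathwayError(f"bad pathway row {ln!r}: {exc}") from exc
    return PathwayModel(steps, dispensable_enzymes or set())


def load_default_pathway(hdh_dispensable: bool = False) -> PathwayModel:
    """The bundled 12-enzyme HS pathway.

    ``hdh_dispensable=True`` adds HDH to the dispensable set: silencing HDH has
    been reported not to abolish hyoscyamine accumulation, so whether its
    absence is compatible with production is left as a switch rather than a
    guess (default: HDH required, matching the producer species, which all
    retain it).
    """
    ref = resources.files("tropanevo.data").joinpath("hs_pathway.tsv")
    with resources.as_file(ref) as p:
        model = load_pathway(p)
    if hdh_dispensable:
        model.dispensable_enzymes.add("HDH")
    return model


def hs_exclusive_steps(model: PathwayModel) -> list[PathwayStep]:
    """The contiguous terminal segment exclusive to HS production.

    Membership is by the ``medicinal`` segment tag; in the bundled model this
    is the five final steps beginning at TRI.
    """
    steps = [s for s in model.steps if s.segment == "medicinal"]
    if not steps:
        warnings.warn("pathway model has no medicinal (HS-exclusive) segment")
        return []
    if not any(s.enzyme_symbol == "TRI" for s in model.steps):
        raise PathwayError("model lacks a TRI step")
    return steps


def producer_phenotype(model: PathwayModel, states: dict[str, str]) -> bool:
    """True iff every non-dispensable enzyme is in the ``intact`` state.

    ``states`` maps each enzyme symbol to one of intact / pseudogene / absent;
    pseudogene and absent both count as non-functional.
    """
    for enzyme in model.enzymes:
        if enzyme not in states:
            raise KeyError(f"state missing for enzyme {enzyme!r}")
        state = states[enzyme]
        if state not in VALID_STATES:
            raise ValueError(f"bad functional state {state!r} for {enzyme}")
        if enzyme in model.dispensable_enzymes:
            continue
        if state != "intact":
            return False
    return True
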