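"""Drug-likeness gating for screening libraries.

Descriptors follow the classic Lipinski conventions: HBD = OH + NH hydrogen
count, HBA = N + O atom count, with logP (Crippen), TPSA (Ertl) and a
Delaney-style ESOL solubility estimate from atomic-contribution schemes.

The absorption / solubility / blood–brain-barrier levels are a transparent
descriptor-based surrogate for the proprietary QSAR categories used by
commercial suites, with the same categorical interface (absorption 0–3,
solubility 0–5, BBB 0–4).  Level semantics are documented on
:class:`AdmetRuleset`; outputs from this surrogate should be labelled as
such when reported next to vendor-tool levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structures import Library, SmallMolecule

__all__ = [
    "DescriptorSet",
    "AdmetLevels",
    "AdmetRuleset",
    "compute_descriptors",
    "rule_of_five",
    "admet_levels",
    "filter_library",
    "FilterReport",
]


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors of one compound."""

    molecular_weight: float  # Da, average
    logp: float
    hbd_count: int  # OH + NH hydrogens
    hba_count: int  # N + O atoms
    tpsa: float  # Å²
    rotatable_bonds: int
    logs: float  # ESOL aqueous solubility estimate, log10(mol/L)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be > 0")
        if min(self.hbd_count, self.hba_count, self.rotatable_bonds) < 0:
            raise ValueError("descriptor counts must be ≥ 0")


@dataclass(frozen=True)
class AdmetLevels:
    """Categorical drug-likeness levels (surrogate semantics).

    absorption_level: 0 good (inside the TPSA/logP ellipse) … 3 very poor.
    solubility_level: 0 insoluble … 5 very soluble (3 = good).
    bbb_level: 0 very high brain penetration … 3 low, 4 undefined/outside.
    """

    bbb_level: int
    solubility_level: int
    absorption_level: int

    def __post_init__(self) -> None:
        if not (0 <= self.bbb_level <= 4):
            raise ValueError("bbb_level out of range 0–4")
        if not (0 <= self.solubility_level <= 5):
            raise ValueError("solubility_level out of range 0–5")
        if not (0 <= self.absorption_level <= 3):
            raise ValueError("absorption_level out of range 0–3")


@dataclass
class AdmetRuleset:
    """Bin edges for the surrogate ADMET levels.

    Absorption uses an Egan-style 95% ellipse on (TPSA, logP), centered at
    the origin with semi-axes ``absorption_tpsa`` / ``absorption_logp``;
    level k means outside the k-fold inflated ellipse (0 = inside).
    Solubility bins ESOL logS at −8/−6/−4/−2/0 (level 3 = logS in (−4, −2],
    the classic "good" band).  BBB bins TPSA at 40/60/90/140 Å² — level 3
    (low penetration) is the desirable class for a non-CNS target.
    """

    absorption_tpsa: float = 131.6
    absorption_logp: float = 5.88
    solubility_edges: tuple = (-8.0, -6.0, -4.0, -2.0, 0.0)
    bbb_tpsa_edges: tuple = (40.0, 60.0, 90.0, 140.0)

    @classmethod
    def permissive(cls, levels: tuple[int, int, int] = (3, 3, 0)) -> "AdmetRuleset":
        """Degenerate config under which every molecule gets ``levels``."""
        ruleset = cls(
            absorption_tpsa=1e9,
            absorption_logp=1e9,
            solubility_edges=(-1e9,) * (levels[1]) + (1e9,) * (5 - levels[1]),
            bbb_tpsa_edges=(-1e9,) * levels[0] + (1e9,) * (4 - levels[0]),
        )
        return ruleset


def compute_descriptors(mol: SmallMolecule) -> DescriptorSet:
    """Descriptor set via RDKit contribution schemes (Crippen logP, Ertl
    TPSA, Delaney ESOL logS)."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    try:
        rd = mol.to_rdkit()
    except Exception as exc:
        raise ValueError(f"molecule {mol.id!r} is not parseable: {exc}") from exc

    mw = Descriptors.MolWt(rd)
    logp = Crippen.MolLogP(rd)
    tpsa = Descriptors.TPSA(rd)
    rot = Lipinski.NumRotatableBonds(rd)
    heavy = rd.GetNumHeavyAtoms()
    aromatic = sum(1 for a in rd.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    logs = 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rot - 0.74 * ap
    return DescriptorSet(
        molecular_weight=mw,
        logp=logp,
        hbd_count=Lipinski.NHOHCount(rd),
        hba_count=Lipinski.NOCount(rd),
        tpsa=tpsa,
        rotatable_bonds=rot,
        logs=logs,
    )


def rule_of_five(d: DescriptorSet) -> tuple[bool, list[str]]:
    """Hard Rule-of-5 gate with strict inequalities: pass iff MW < 500 Da,
    logP < 5, HBD < 5 and HBA < 10.  Returns (pass, violated rules)."""
    violations = []
    if not d.molecular_weight < 500.0:
        violations.append("MW")
    if not d.logp < 5.0:
        violations.append("LOGP")
    if not d.hbd_count < 5:
        violations.append("HBD")
    if not d.hba_count < 10:
        violations.append("HBA")
    return (not violations, violations)


def admet_levels(d: DescriptorSet, ruleset: AdmetRuleset | None = None) -> AdmetLevels:
    """Pure, deterministic categorical levels from the descriptor set."""
    ruleset = ruleset or AdmetRuleset()

    r2 = (d.tpsa / ruleset.absorption_tpsa) ** 2 + (d.logp / ruleset.absorption_logp) ** 2
    if r2 <= 1.0:
        absorption = 0
    elif r2 <= 1.5**2:
        absorption = 1
    elif r2 <= 2.0**2:
        absorption = 2
    else:
        absorption = 3

    solubility = 0
    for edge in ruleset.solubility_edges:
        if d.logs > edge:
            solubility += 1

    bbb = 0
    for edge in ruleset.bbb_tpsa_edges:
        if d.tpsa > edge:
            bbb += 1

    return AdmetLevels(
        bbb_level=bbb, solubility_level=solubility, absorption_level=absorption
    )


@dataclass
class FilterReport:
    """Per-stage survivor counts of the sequential ADMET → Ro5 gate."""

    n_input: int
    n_post_admet: int
    n_post_ro5: int
    violations: dict[str, list[str]] = field(default_factory=dict)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_input, self.n_post_admet, self.n_post_ro5)


def filter_library(
    library: Library | list[SmallMolecule],
    require_levels: tuple[int, int, int] | None = (3, 3, 0),
    require_ro5: bool = True,
    ruleset: AdmetRuleset | None = None,
) -> tuple[list[SmallMolecule], FilterReport]:
    """Sequential drug-likeness gate: ADMET levels first, then Rule of 5.

    ``require_levels`` is the exact (BBB, solubility, absorption) triple a
    compound must score, or None to skip the ADMET stage.  Returns the kept
    molecules and a per-stage report with per-molecule Ro5 violations.
    """
    molecules = list(library)
    report = FilterReport(len(molecules), 0, 0)

    post_admet: list[SmallMolecule] = []
    descriptors: dict[str, DescriptorSet] = {}
    for mol in molecules:
        d = compute_descriptors(mol)
        descriptors[mol.id] = d
        if require_levels is not None:
            levels = admet_levels(d, ruleset)
            if (
                levels.bbb_level,
                levels.solubility_level,
                levels.absorption_level,
            ) != tuple(require_levels):
                report.violations[mol.id] = ["ADMET"]
                continue
        post_admet.append(mol)
    report.n_post_admet = len(post_admet)

    kept: list[SmallMolecule] = []
    for mol in post_admet:
        if require_ro5:
            ok, violations = rule_of_five(descriptors[mol.id])
            if not ok:
                report.violations[mol.id] = violations
                continue
        kept.append(mol)
    report.n_post_ro5 = len(kept)
    return kept, report
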