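"""Drug-likeness rules for PPI inhibitors: Ro5, Ro5-1, QED, Rule-of-Four.

Four instruments are implemented over molecular property tables:

* Lipinski's rule of five (Ro5): Mwt <= 500 Da, LogP <= 5, HBD <= 5,
  HBA <= 10; a molecule is drug-like when it violates none of the four.
* Ro5-1: the relaxed PPI variant that tolerates a single Ro5 violation.
* QED: the quantitative estimate of drug-likeness -- the weighted geometric
  mean of eight desirability values (Mwt, ALogP, HBA, HBD, PSA, RotB,
  aromatic rings, structural alerts), each computed with the published
  asymmetric-double-sigmoid (ADS) desirability functions of Bickerton et
  al.; drug-like when QED >= 0.5.
* Rule-of-Four: the descriptive PPI-inhibitor profile Mwt > 400 Da,
  ALogP > 4, HBA > 4, rings > 4 (strict inequalities).

The module consumes property tables directly so that no chemistry toolkit
is required; computing properties from SMILES/SDF is delegated to a
pluggable descriptor backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MoleculeProperties",
    "RuleResult",
    "QEDParameters",
    "ADS_PARAMETERS",
    "QED_WEIGHTS_CANONICAL",
    "ads",
    "ro5_violations",
    "is_druglike_ro5_minus_1",
    "qed",
    "rule_of_four_profile",
    "evaluate_molecule",
    "audit_set",
    "properties_from_frame",
]

#: Column order of the interchange TSV property table.
PROPERTY_COLUMNS = ("id", "mwt", "hbd", "hba", "logp", "psa", "rotb", "arom_rings", "alerts")


@dataclass(frozen=True)
class MoleculeProperties:
    """The eight QED descriptors (Lipinski's quantities are a subset)."""

    id: str
    mwt: float
    hbd: int
    hba: int
    logp: float
    psa: float | None = None
    rotb: int | None = None
    arom_rings: int | None = None
    alerts: int | None = None

    def __post_init__(self) -> None:
        if self.mwt <= 0:
            raise ValueError("molecular weight must be positive")
        for name in ("hbd", "hba", "rotb", "arom_rings", "alerts"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def require_qed_fields(self) -> None:
        missing = [
            f for f in ("psa", "rotb", "arom_rings", "alerts") if getattr(self, f) is None
        ]
        if missing:
            raise ValueError(f"QED needs descriptors {missing} for molecule {self.id!r}")


# ---------------------------------------------------------------------------
# QED desirability machinery
# ---------------------------------------------------------------------------

#: Published ADS coefficients (a, b, c, d, e, f, dmax) per descriptor
#: (Bickerton et al. 2012, quantitative estimate of drug-likeness).
ADS_PARAMETERS: dict[str, tuple[float, ...]] = {
    "mwt":        (2.817065973, 392.5754953, 290.7489764, 2.419764353, 49.22325677, 65.37051707, 104.9805561),
    "logp":       (3.172690585, 137.8624751, 2.534937431, 4.581497897, 0.822739154, 0.576295591, 131.3186604),
    "hba":        (2.948620388, 160.4605972, 3.615294657, 4.435986202, 0.290141953, 1.300669958, 148.7763046),
    "hbd":        (1.618662227, 1010.051101, 0.985094388, 0.000000001, 0.713820843, 0.920922555, 258.1632616),
    "psa":        (1.876861559, 125.2232657, 62.90773554, 87.83366614, 12.01999824, 28.51324732, 104.5686167),
    "rotb":       (0.010000000, 272.4121427, 2.558379970, 1.565547684, 1.271567166, 2.758063707, 105.4420403),
    "arom_rings": (3.217788970, 957.7374108, 2.274627939, 0.000000001, 1.317690384, 0.375760881, 312.3372610),
    "alerts":     (0.010000000, 1199.094025, -0.09002883, 0.000000001, 0.185904477, 0.875193782, 417.7253140),
}

#: Canonical mean-weight set of the original QED publication.
QED_WEIGHTS_CANONICAL: dict[str, float] = {
    "mwt": 0.66, "logp": 0.46, "hba": 0.05, "hbd": 0.61,
    "psa": 0.06, "rotb": 0.65, "arom_rings": 0.48, "alerts": 0.95,
}

_DESIRABILITY_FLOOR = 1e-6


def ads(x: float, coeffs: tuple[float, ...]) -> float:
    """Asymmetric double sigmoid desirability, normalized to its maximum."""
    a, b, c, d, e, f, dmax = coeffs
    raw = a + b / (1.0 + math.exp(-(x - c + d / 2.0) / e)) * (
        1.0 - 1.0 / (1.0 + math.exp(-(x - c - d / 2.0) / f))
    )
    return raw / dmax


@dataclass(frozen=True)
class QEDParameters:
    """Desirability coefficients and per-descriptor weights."""

    ads: dict[str, tuple[float, ...]]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.ads) != set(self.weights):
            raise ValueError("ads and weights must cover the same descriptors")
        if any(w < 0 for w in self.weights.values()) or not any(self.weights.values()):
            raise ValueError("weights must be >= 0 and not all zero")

    @classmethod
    def unweighted(cls) -> "QEDParameters":
        return cls(ads=dict(ADS_PARAMETERS), weights={k: 1.0 for k in ADS_PARAMETERS})

    @classmethod
    def canonical(cls) -> "QEDParameters":
        return cls(ads=dict(ADS_PARAMETERS), weights=dict(QED_WEIGHTS_CANONICAL))


def qed(props: MoleculeProperties, params: QEDParameters | None = None) -> float:
    """Weighted geometric mean of the eight desirability values.

    Desirabilities are floored at 1e-6 before the logarithm so that a
    descriptor far outside its preferred range drives the score toward
    zero without a numeric domain error.
    """
    params = params or QEDParameters.unweighted()
    props.require_qed_fields()
    total_w = sum(params.weights.values())
    acc = 0.0
    for name, coeffs in params.ads.items():
        d = max(ads(float(getattr(props, name)), coeffs), _DESIRABILITY_FLOOR)
        acc += params.weights[name] * math.log(d)
    return math.exp(acc / total_w)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def ro5_violations(props: MoleculeProperties) -> int:
    """Number of Lipinski conditions violated (0-4)."""
    return sum(
        (
            props.mwt > 500.0,
            props.logp > 5.0,
            props.hbd > 5,
            props.hba > 10,
        )
    )


def is_druglike_ro5_minus_1(props: MoleculeProperties) -> bool:
    """Relaxed PPI rule: drug-like with at most one Ro5 violation."""
    return ro5_violations(props) <= 1


@dataclass(frozen=True)
class RuleOfFourProfile:
    large: bool        # Mwt > 400 Da
    hydrophobic: bool  # ALogP > 4
    unsaturated: bool  # HBA > 4
    ringy: bool        # rings > 4

    @property
    def matches(self) -> bool:
        return self.large and self.hydrophobic and self.unsaturated and self.ringy


def rule_of_four_profile(props: MoleculeProperties) -> RuleOfFourProfile:
    """The descriptive Rule-of-Four PPI-inhibitor profile (all strict)."""
    if props.arom_rings is None:
        raise ValueError("rule_of_four needs a ring count")
    return RuleOfFourProfile(
        large=props.mwt > 400.0,
        hydrophobic=props.logp > 4.0,
        unsaturated=props.hba > 4,
        ringy=props.arom_rings > 4,
    )


@dataclass(frozen=True)
class RuleResult:
    id: str
    violations: int
    pass_ro5: bool
    pass_ro5_minus_1: bool
    qed: float | None
    pass_qed: bool | None
    rule_of_four: bool | None

    def __post_init__(self) -> None:
        if self.pass_ro5 and not self.pass_ro5_minus_1:
            raise ValueError("Ro5 compliance implies Ro5-1 compliance")


def evaluate_molecule(
    props: MoleculeProperties,
    params: QEDParameters | None = None,
    ro5_max_violations: int = 0,
) -> RuleResult:
    """All rule outcomes for one molecule.

    ``ro5_max_violations`` selects how strict the plain-Ro5 flag is (the
    conventional reading is zero violations; a documented switch allows
    the <=1 reading used by some descriptor suites).
    """
    v = ro5_violations(props)
    has_qed = all(
        getattr(props, f) is not None for f in ("psa", "rotb", "arom_rings", "alerts")
    )
    q = qed(props, params) if has_qed else None
    ro4 = rule_of_four_profile(props).matches if props.arom_rings is not None else None
    return RuleResult(
        id=props.id,
        violations=v,
        pass_ro5=v <= ro5_max_violations,
        pass_ro5_minus_1=v <= 1,
        qed=q,
        pass_qed=(q >= 0.5) if q is not None else None,
        rule_of_four=ro4,
    )


def properties_from_frame(frame: pd.DataFrame) -> list[MoleculeProperties]:
    """Parse a property table (TSV layout: id, mwt, hbd, hba, logp, psa,
    rotb, arom_rings, alerts) into typed records."""
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        out.append(
            MoleculeProperties(
                id=str(d["id"]),
                mwt=float(d["mwt"]),
                hbd=int(d["hbd"]),
                hba=int(d["hba"]),
                logp=float(d["logp"]),
                psa=float(d["psa"]) if "psa" in d and pd.notna(d["psa"]) else None,
                rotb=int(d["rotb"]) if "rotb" in d and pd.notna(d["rotb"]) else None,
                arom_rings=int(d["arom_rings"]) if "arom_rings" in d and pd.notna(d["arom_rings"]) else None,
                alerts=int(d["alerts"]) if "alerts" in d and pd.notna(d["alerts"]) else None,
            )
        )
    return out


def audit_set(
    molecules: list[MoleculeProperties],
    targets: dict[str, str] | None = None,
    params: QEDParameters | None = None,
    ro5_max_violations: int = 0,
) -> pd.DataFrame:
    """Counts and percentages of molecules passing each rule.

    One row per target group (plus an ``all`` row when grouping is used);
    percentages are reported to one decimal.
    """
    if not molecules:
        raise ValueError("cannot audit an empty molecule set")
    results = [evaluate_molecule(m, params, ro5_max_violations) for m in molecules]
    groups: dict[str, list[RuleResult]] = {}
    if targets:
        for res in results:
            groups.setdefault(targets.get(res.id, "unassigned"), []).append(res)
        if len(groups) > 1:
            groups["all"] = results
    else:
        groups["all"] = results

    rows = []
    for name in sorted(groups):
        rs = groups[name]
        n = len(rs)
        n_ro5 = sum(r.pass_ro5 for r in rs)
        n_ro5m1 = sum(r.pass_ro5_minus_1 for r in rs)
        with_qed = [r for r in rs if r.pass_qed is not None]
        n_qed = sum(r.pass_qed for r in with_qed)
        rows.append(
            {
                "group": name,
                "n_molecules": n,
                "n_ro5": n_ro5,
                "pct_ro5": round(100.0 * n_ro5 / n, 1),
                "n_qed": n_qed,
                "pct_qed": round(100.0 * n_qed / len(with_qed), 1) if with_qed else None,
                "n_ro5_minus_1": n_ro5m1,
                "pct_ro5_minus_1": round(100.0 * n_ro5m1 / n, 1),
            }
        )
    return pd.DataFrame(rows)


def property_means(
    molecules: list[MoleculeProperties],
    params: QEDParameters | None = None,
) -> pd.DataFrame:
    """Mean +/- sample SD of HBA, HBD, LogP, Mwt and QED (survey layout)."""
    import numpy as np

    rows = {}
    for name in ("hba", "hbd", "logp", "mwt"):
        vals = np.array([float(getattr(m, name)) for m in molecules])
        rows[name] = {"mean": vals.mean(), "sd": vals.std(ddof=1) if len(vals) > 1 else None}
    qeds = []
    for m in molecules:
        try:
            qeds.append(qed(m, params))
        except ValueError:
            pass
    if qeds:
        arr = np.array(qeds)
        rows["qed"] = {"mean": arr.mean(), "sd": arr.std(ddof=1) if len(arr) > 1 else None}
    return pd.DataFrame(rows).T
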