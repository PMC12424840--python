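"""Per-compound druggability metrics and NP-likeness imputation.

Three complementary drug-likeness views are computed for every compound with
a parseable structure:

* **Lipinski Rule of Five violations** — how many of the four classical
  thresholds (MW > 500 Da, logP > 5, H-bond donors > 5, acceptors > 10) a
  molecule breaches, 0–4;
* **weighted QED** — the exponentially-weighted geometric mean of eight
  property desirability functions (asymmetric double sigmoids), in (0, 1];
  the desirability parameterisation and weights ship as an editable data
  file, so alternative weight sets are a configuration change;
* **NP-likeness** — a score on the [−5, +5] scale expressing how
  natural-product-like a structure is.  Observed scores come in as data; for
  compounds without one, a random-forest regressor over a 2054-dimensional
  feature vector (2048-bit ECFP4 fingerprint plus six physicochemical
  descriptors) imputes the score.  Observed values are never overwritten.

"Polarizable surface area" here is computed as topological polar surface
area (TPSA), the standard topological descriptor in this feature family.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem import QED as _rdkit_qed
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

RDLogger.DisableLog("rdApp.*")

FINGERPRINT_BITS = 2048
NP_SCALE = (-5.0, 5.0)

#: desirable bands used in the four-set comparison
WQED_BAND = (0.4, 0.7)
NP_BAND = (0.5, 2.5)


class StructureError(ValueError):
    """Unparseable structure input; carries the offending string."""

    def __init__(self, smiles: str):
        super().__init__(f"cannot parse structure: {smiles!r}")
        self.smiles = smiles


@dataclass
class DescriptorVector:
    """The seven feature groups used throughout the druggability analyses."""

    molecular_weight: float
    h_bond_acceptors: int
    h_bond_donors: int
    polar_surface_area: float
    rotatable_bonds: int
    alogp: float
    ecfp4: np.ndarray  # 2048-bit uint8 vector

    def features(self) -> np.ndarray:
        """Flat model feature vector: 2048 fingerprint bits + 6 descriptors."""
        return np.concatenate([
            self.ecfp4.astype(np.float64),
            [self.molecular_weight, self.h_bond_acceptors, self.h_bond_donors,
             self.polar_surface_area, self.rotatable_bonds, self.alogp],
        ])


@dataclass
class DruggabilityRecord:
    compound_key: str
    descriptors: DescriptorVector
    ro5_violations: int
    wqed: float
    np_likeness: float | None = None
    np_source: str | None = None  # observed | imputed


def compute_descriptors(
    smiles: str, nplus_o_counts: bool = False
) -> DescriptorVector:
    """Descriptor vector for one SMILES string.

    The fingerprint is a circular (Morgan/ECFP4) fingerprint of radius 2
    folded to 2048 bits.  H-bond donor/acceptor counts use the
    pharmacophore-style definitions by default; ``nplus_o_counts`` switches
    to plain N+O / NH+OH counting.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    if nplus_o_counts:
        hba = rdMolDescriptors.CalcNumLipinskiHBA(mol)
        hbd = rdMolDescriptors.CalcNumLipinskiHBD(mol)
    else:
        hba = rdMolDescriptors.CalcNumHBA(mol)
        hbd = rdMolDescriptors.CalcNumHBD(mol)
    fp = rdMolDescriptors.GetMorganFingerprintAsBitVect(
        mol, radius=2, nBits=FINGERPRINT_BITS
    )
    arr = np.zeros(FINGERPRINT_BITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return DescriptorVector(
        molecular_weight=Descriptors.MolWt(mol),
        h_bond_acceptors=hba,
        h_bond_donors=hbd,
        polar_surface_area=rdMolDescriptors.CalcTPSA(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        alogp=Crippen.MolLogP(mol),
        ecfp4=arr,
    )


def lipinski_violations(d: DescriptorVector) -> int:
    """Count of Rule of Five breaches; thresholds are strict inequalities."""
    return sum([
        d.molecular_weight > 500,
        d.alogp > 5,
        d.h_bond_donors > 5,
        d.h_bond_acceptors > 10,
    ])


# ---------------------------------------------------------------------------
# weighted QED
# ---------------------------------------------------------------------------

QED_PROPERTIES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")


@dataclass
class QEDParameters:
    """ADS desirability coefficients and weights for the eight properties."""

    ads: dict[str, tuple[float, ...]]  # property -> (a..f, dmax)
    weights: dict[str, float]

    @classmethod
    def default(cls) -> "QEDParameters":
        ref = resources.files("pipermine.data") / "qed_params.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QEDParameters":
        ads: dict[str, tuple[float, ...]] = {}
        weights: dict[str, float] = {}
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                prop = row["property"]
                ads[prop] = tuple(
                    float(row[k]) for k in ("a", "b", "c", "d", "e", "f", "dmax")
                )
                weights[prop] = float(row["weight"])
        missing = set(QED_PROPERTIES) - set(ads)
        if missing:
            raise ValueError(f"QED parameter file missing properties {missing}")
        return cls(ads=ads, weights=weights)


def _ads(x: float, params: tuple[float, ...]) -> float:
    """Asymmetric double sigmoid desirability, normalised to (0, 1]."""
    a, b, c, d, e, f, dmax = params
    return (
        a
        + b / (1 + math.exp(-(x - c + d / 2) / e))
        * (1 - 1 / (1 + math.exp(-(x - c - d / 2) / f)))
    ) / dmax


def qed_properties(smiles_or_mol) -> dict[str, float]:
    """The eight QED input properties for one molecule."""
    mol = smiles_or_mol
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
        if mol is None:
            raise StructureError(smiles_or_mol)
    props = _rdkit_qed.properties(mol)
    return dict(zip(QED_PROPERTIES, props))


def weighted_qed(
    smiles_or_mol,
    params: QEDParameters | None = None,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Exponentially-weighted geometric mean of property desirabilities.

    ``exp( Σ w_i · ln d_i / Σ w_i )`` over the eight properties; equals the
    plain geometric mean when all weights are equal.  Result in (0, 1].
    """
    if params is None:
        params = QEDParameters.default()
    w = dict(params.weights)
    if weights is not None:
        w.update(weights)
    props = qed_properties(smiles_or_mol)
    num = 0.0
    den = 0.0
    for prop in QED_PROPERTIES:
        d = max(_ads(props[prop], params.ads[prop]), 1e-10)
        num += w[prop] * math.log(d)
        den += w[prop]
    return math.exp(num / den)


def combine_desirabilities(
    desirabilities: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """The bare weighted-geometric-mean combination rule."""
    if weights is None:
        weights = [1.0] * len(desirabilities)
    num = sum(w * math.log(max(d, 1e-10)) for d, w in zip(desirabilities, weights))
    return math.exp(num / sum(weights))


# ---------------------------------------------------------------------------
# NP-likeness imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputerConfig:
    """Random-forest imputer hyperparameters.

    One seed governs the train/validation split, the tree bootstrap and the
    feature subsampling.
    """

    n_trees: int = 150
    max_depth: int = 80
    train_fraction: float = 0.85
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ImputerEvaluation:
    r_squared: float
    mse: float
    n_train: int
    n_valid: int


@dataclass
class NPImputer:
    model: RandomForestRegressor
    config: ImputerConfig
    evaluation: ImputerEvaluation

    def predict(self, descriptors: Iterable[DescriptorVector]) -> np.ndarray:
        X = np.vstack([d.features() for d in descriptors])
        return self.model.predict(X)


def train_np_imputer(
    labeled: Sequence[tuple[DescriptorVector, float]],
    config: ImputerConfig,
) -> NPImputer:
    """Fit the NP-likeness random forest and evaluate on a held-out split.

    The labeled records are split at ``train_fraction`` with the configured
    seed; the forest (``n_trees`` depth-capped trees) is fit on the training
    part and R²/MSE are reported on the held-out part.
    """
    if len(labeled) < 10:
        raise ValueError(f"need >= 10 labeled records, got {len(labeled)}")
    for i, (_, y) in enumerate(labeled):
        if not math.isfinite(y):
            raise ValueError(f"non-finite NP-likeness label at record {i}")
    X = np.vstack([d.features() for d, _ in labeled])
    y = np.array([label for _, label in labeled])
    X_train, X_valid, y_train, y_valid = train_test_split(
        X, y, train_size=config.train_fraction, random_state=config.random_seed
    )
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.random_seed,
        n_jobs=1,
    )
    model.fit(X_train, y_train)
    pred = model.predict(X_valid)
    evaluation = ImputerEvaluation(
        r_squared=r2_score(y_valid, pred),
        mse=mean_squared_error(y_valid, pred),
        n_train=len(y_train),
        n_valid=len(y_valid),
    )
    return NPImputer(model=model, config=config, evaluation=evaluation)


def impute_np_likeness(
    imputer: NPImputer, records: Sequence[DruggabilityRecord]
) -> tuple[list[DruggabilityRecord], float]:
    """Fill missing NP-likeness scores in place of Nones.

    Records with an observed score pass through untouched.  Returns the
    records plus the fraction of them whose score is imputed.
    """
    missing = [r for r in records if r.np_likeness is None]
    if missing:
        preds = imputer.predict([r.descriptors for r in missing])
        for rec, pred in zip(missing, preds):
            rec.np_likeness = float(pred)
            rec.np_source = "imputed"
    for rec in records:
        if rec.np_source is None and rec.np_likeness is not None:
            rec.np_source = "observed"
    imputed_fraction = (
        sum(1 for r in records if r.np_source == "imputed") / len(records)
        if records else 0.0
    )
    return list(records), imputed_fraction


def score_compounds(
    structures: Mapping[str, str],
    observed_np: Mapping[str, float] | None = None,
    qed_params: QEDParameters | None = None,
) -> tuple[list[DruggabilityRecord], list[str]]:
    """Descriptors, RO5 count and wQED for every parseable structure.

    Returns the records (sorted by compound_key) and the keys skipped for
    unparseable structures.
    """
    observed_np = observed_np or {}
    records: list[DruggabilityRecord] = []
    skipped: list[str] = []
    for key in sorted(structures):
        try:
            d = compute_descriptors(structures[key])
            wq = weighted_qed(structures[key], qed_params)
        except StructureError:
            skipped.append(key)
            continue
        obs = observed_np.get(key)
        records.append(
            DruggabilityRecord(
                compound_key=key,
                descriptors=d,
                ro5_violations=lipinski_violations(d),
                wqed=wq,
                np_likeness=obs,
                np_source="observed" if obs is not None else None,
            )
        )
    return records, skipped


# ---------------------------------------------------------------------------
# four-set comparison
# ---------------------------------------------------------------------------

def compare_sets(
    records: Sequence[DruggabilityRecord],
    set_definitions: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Distribution summary of wQED / NP-likeness / RO5 per named set.

    Sets may overlap.  Per set: n, mean and quartiles of wQED and
    NP-likeness, the fraction inside the desirable bands (wQED 0.4–0.7,
    NP-likeness 0.5–2.5), and the proportions with zero vs at least one RO5
    violation.  An empty set yields a row with n = 0 and NaN statistics.
    """
    if not set_definitions:
        raise ValueError("at least one named set is required")
    by_key = {r.compound_key: r for r in records}
    rows = []
    for name in sorted(set_definitions):
        members = [by_key[k] for k in set_definitions[name] if k in by_key]
        n = len(members)
        if n == 0:
            rows.append({"set": name, "n": 0})
            continue
        wq = np.array([r.wqed for r in members])
        np_scores = np.array(
            [r.np_likeness for r in members if r.np_likeness is not None]
        )
        row = {
            "set": name,
            "n": n,
            "wqed_mean": wq.mean(),
            "wqed_q1": np.percentile(wq, 25),
            "wqed_median": np.percentile(wq, 50),
            "wqed_q3": np.percentile(wq, 75),
            "wqed_in_band": float(
                np.mean((wq >= WQED_BAND[0]) & (wq <= WQED_BAND[1]))
            ),
            "ro5_zero": float(
                np.mean([r.ro5_violations == 0 for r in members])
            ),
            "ro5_one_plus": float(
                np.mean([r.ro5_violations >= 1 for r in members])
            ),
        }
        if len(np_scores):
            row.update(
                np_mean=np_scores.mean(),
                np_q1=np.percentile(np_scores, 25),
                np_median=np.percentile(np_scores, 50),
                np_q3=np.percentile(np_scores, 75),
                np_in_band=float(
                    np.mean((np_scores >= NP_BAND[0]) & (np_scores <= NP_BAND[1]))
                ),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def records_table(records: Sequence[DruggabilityRecord]) -> pd.DataFrame:
    rows = [
        {
            "compound_key": r.compound_key,
            "molecular_weight": r.descriptors.molecular_weight,
            "h_bond_acceptors": r.descriptors.h_bond_acceptors,
            "h_bond_donors": r.descriptors.h_bond_donors,
            "polar_surface_area": r.descriptors.polar_surface_area,
            "rotatable_bonds": r.descriptors.rotatable_bonds,
            "alogp": r.descriptors.alogp,
            "ro5_violations": r.ro5_violations,
            "wqed": r.wqed,
            "np_likeness": r.np_likeness,
            "np_source": r.np_source,
        }
        for r in sorted(records, key=lambda r: r.compound_key)
    ]
    return pd.DataFrame(rows)
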