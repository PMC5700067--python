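"""Standardized chemotactic-index (CI) dataset and response classification.

The packaged dataset holds transwell microchemotaxis results for 48
recombinant chemokines against five resting murine lymphocyte populations
(pan T, CD4+ T, CD8+ T, B, NK), each assayed at 0, 10, 100 and 1000 ng/mL
with n = 4 replicate wells.  The chemotactic index normalizes directional
migration to the chemokinesis baseline measured in control wells:

    CI = (fraction of seeded cells migrating to the test condition)
         / (fraction migrating to control medium)

so CI = 1 means no attraction beyond random motility.  Two
(chemokine, population) pairs -- CCL19/NK and CCL21/NK -- were not
determined and are stored as explicit missing records, never as zeros.

The ``±`` column of the source table is stored verbatim as ``ci_sd``; the
source does not state whether it denotes SD or SEM.  One printed anomaly is
preserved as-is: the Chemerin/NK 0 ng/mL control row reads 0.67 ± 0.47
rather than the normalized 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = [
    "CellPopulation",
    "Significance",
    "ResponseCategory",
    "CIRecord",
    "ResponseCall",
    "ChemokinePanel",
    "compute_ci",
    "load_panel",
    "ttest_vs_control",
    "classify_response",
]


class CellPopulation(str, Enum):
    """Lymphocyte populations assayed in the panel."""

    panT = "panT"
    CD4T = "CD4T"
    CD8T = "CD8T"
    B = "B"
    NK = "NK"


class Significance(str, Enum):
    """Printed significance level of a dose versus the 0 ng/mL control."""

    ns = "ns"
    p05 = "p<0.05"
    p01 = "p<0.01"
    p001 = "p<0.001"
    p0001 = "p<0.0001"

    @property
    def is_significant(self) -> bool:
        return self is not Significance.ns


class ResponseCategory(str, Enum):
    """Summary response call for one chemokine x population.

    ``plus``: significant at >= 1 dose and CI > 5 at >= 1 dose.
    ``minus_plus``: significant at >= 1 dose but CI never above 5.
    ``minus``: no significant dose.  ``nd``: not determined.
    """

    minus = "-"
    minus_plus = "-/+"
    plus = "+"
    nd = "ND"


#: Doses (ng/mL) at which each chemokine was assayed; 0 is the control.
DOSES = (0, 10, 100, 1000)

#: Chemokine lookup aliases; the CCL9/10 reagent is tabulated as CCL9.
_ALIASES = {"CCL9/10": "CCL9", "SDF1B": "CXCL12", "SDF1b": "CXCL12"}

#: Control (0 ng/mL) cell that the source prints un-normalized.
_CONTROL_ANOMALY = ("Chemerin", "NK")

#: Chemokinesis placeholders (fraction of seeded cells migrating in control
#: wells).  These are synthetic order-of-magnitude defaults reflecting only
#: that resting NK cells show markedly higher baseline motility than the
#: other resting populations; they are not measured values.
DEFAULT_CHEMOKINESIS = {
    CellPopulation.panT: 0.02,
    CellPopulation.CD4T: 0.02,
    CellPopulation.CD8T: 0.02,
    CellPopulation.B: 0.02,
    CellPopulation.NK: 0.10,
}


@dataclass(frozen=True)
class CIRecord:
    """One chemokine x population x dose assay result."""

    chemokine: str
    cell_population: CellPopulation
    concentration: int  # ng/mL
    ci_mean: float | None
    ci_sd: float | None
    n: int
    significance: Significance
    measured: bool

    def __post_init__(self) -> None:
        if self.measured:
            if self.ci_mean is None or self.ci_sd is None:
                raise ValueError("measured record lacks ci_mean/ci_sd")
            if self.ci_mean < 0 or self.ci_sd < 0:
                raise ValueError("ci_mean and ci_sd must be non-negative")
        elif self.ci_mean is not None or self.ci_sd is not None:
            raise ValueError("unmeasured (ND) record must not carry values")


@dataclass(frozen=True)
class ResponseCall:
    chemokine: str
    cell_population: CellPopulation
    category: ResponseCategory


def compute_ci(condition_fraction: float, control_fraction: float) -> float:
    """Chemotactic index: migrated fraction over the chemokinesis baseline.

    Both arguments are fractions of seeded cells in (0, 1]; a zero control
    fraction leaves the index undefined.
    """
    for name, frac in (("condition_fraction", condition_fraction),
                       ("control_fraction", control_fraction)):
        if not 0.0 <= frac <= 1.0 or math.isnan(frac):
            raise ValueError(f"{name} must be a fraction in [0, 1], got {frac}")
    if control_fraction == 0.0:
        raise ZeroDivisionError(
            "control migration fraction is zero: chemotactic index undefined")
    return condition_fraction / control_fraction


def ttest_vs_control(ci_mean: float, ci_sd: float,
                     control_mean: float, control_sd: float,
                     n: int = 4) -> float:
    """Two-sided unpaired Student t-test p-value from summary statistics.

    Uses the pooled-variance (equal-variance Student) form with ``n``
    observations per group, df = 2n - 2, matching a per-dose comparison
    against the 0 ng/mL control.  If both groups have zero variance and
    equal means the statistic is 0/0; p = 1 by convention.
    """
    if n < 2:
        raise ValueError("need at least 2 observations per group")
    if ci_sd < 0 or control_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if ci_sd == 0.0 and control_sd == 0.0:
        return 1.0 if ci_mean == control_mean else 0.0
    res = stats.ttest_ind_from_stats(ci_mean, ci_sd, n,
                                     control_mean, control_sd, n,
                                     equal_var=True)
    return float(res.pvalue)


def classify_response(records: list[CIRecord]) -> ResponseCall:
    """Summary response call from all dose records of one chemokine x population.

    The call uses the stored printed significance levels (the panel's
    summary statistics are too coarse to re-run the underlying per-well
    test exactly): "+" needs a significant dose and a dose with CI > 5,
    "-/+" a significant dose only, "-" neither; ND if unmeasured.
    """
    if not records:
        raise ValueError("empty record set")
    ck = {r.chemokine for r in records}
    pop = {r.cell_population for r in records}
    if len(ck) != 1 or len(pop) != 1:
        raise ValueError("records must cover a single chemokine x population")
    doses = [r for r in records if r.concentration > 0]
    if not any(r.measured for r in doses):
        cat = ResponseCategory.nd
    else:
        any_sig = any(r.significance.is_significant for r in doses if r.measured)
        any_big = any(r.ci_mean > 5 for r in doses if r.measured)
        if any_sig and any_big:
            cat = ResponseCategory.plus
        elif any_sig:
            cat = ResponseCategory.minus_plus
        else:
            cat = ResponseCategory.minus
    return ResponseCall(ck.pop(), pop.pop(), cat)


class ChemokinePanel:
    """The full CI panel with total lookup over measured combinations."""

    def __init__(self, records: list[CIRecord],
                 chemokinesis_baselines: dict[CellPopulation, float] | None = None):
        self.records = records
        self.chemokinesis_baselines = dict(chemokinesis_baselines
                                           or DEFAULT_CHEMOKINESIS)
        self._index: dict[tuple[str, CellPopulation, int], CIRecord] = {}
        for rec in records:
            key = (rec.chemokine, rec.cell_population, rec.concentration)
            if key in self._index:
                raise ValueError(f"duplicate record for {key}")
            self._index[key] = rec
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ChemokinePanel":
        df = pd.read_csv(path)
        required = {"chemokine", "cell_population", "concentration_ng_ml",
                    "ci_mean", "ci_sd", "significance", "measured"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset is missing columns: {sorted(missing)}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                measured = _as_bool(row.measured)
                records.append(CIRecord(
                    chemokine=str(row.chemokine),
                    cell_population=CellPopulation(row.cell_population),
                    concentration=int(row.concentration_ng_ml),
                    ci_mean=float(row.ci_mean) if measured else None,
                    ci_sd=float(row.ci_sd) if measured else None,
                    n=4,
                    significance=(Significance(row.significance) if measured
                                  else Significance.ns),
                    measured=measured,
                ))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"bad dataset row {i + 2}: {exc}") from exc
        return cls(records, **kwargs)

    def _validate(self) -> None:
        for rec in self.records:
            if (rec.measured and rec.concentration == 0 and rec.ci_mean != 1.0
                    and (rec.chemokine, rec.cell_population.value) != _CONTROL_ANOMALY):
                raise ValueError(
                    f"control row not normalized to 1: {rec.chemokine}"
                    f"/{rec.cell_population.value}")

    # -- queries -----------------------------------------------------------

    @property
    def chemokines(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.chemokine, None)
        return list(seen)

    @property
    def populations(self) -> list[CellPopulation]:
        return list(CellPopulation)

    def lookup(self, chemokine: str, population: CellPopulation | str,
               concentration: int) -> CIRecord:
        chemokine = _ALIASES.get(chemokine, chemokine)
        population = CellPopulation(population)
        try:
            return self._index[(chemokine, population, int(concentration))]
        except KeyError:
            raise KeyError(
                f"no record for {chemokine}/{population.value}"
                f"/{concentration} ng/mL") from None

    def combination_records(self, chemokine: str,
                            population: CellPopulation | str) -> list[CIRecord]:
        chemokine = _ALIASES.get(chemokine, chemokine)
        population = CellPopulation(population)
        recs = [r for r in self.records
                if r.chemokine == chemokine and r.cell_population == population]
        if not recs:
            raise KeyError(f"unknown combination {chemokine}/{population.value}")
        return recs

    def classify(self, chemokine: str,
                 population: CellPopulation | str) -> ResponseCall:
        return classify_response(self.combination_records(chemokine, population))

    def n_measured_combinations(self) -> int:
        combos = {(r.chemokine, r.cell_population)
                  for r in self.records if r.measured}
        return len(combos)

    def unmeasured_combinations(self) -> list[tuple[str, CellPopulation]]:
        measured = {(r.chemokine, r.cell_population)
                    for r in self.records if r.measured}
        out = []
        for ck in self.chemokines:
            for pop in CellPopulation:
                if (ck, pop) not in measured:
                    out.append((ck, pop))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "chemokine": r.chemokine,
                "cell_population": r.cell_population.value,
                "concentration_ng_ml": r.concentration,
                "ci_mean": r.ci_mean,
                "ci_sd": r.ci_sd,
                "n": r.n,
                "significance": r.significance.value if r.measured else None,
                "measured": r.measured,
            })
        return pd.DataFrame(rows)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "yes"}


def default_dataset_path() -> Path:
    """Path of the CSV dataset shipped with the package."""
    return Path(resources.files("elnsim").joinpath("data/chemotaxis_ci.csv"))


def load_panel(path: str | Path | None = None, **kwargs) -> ChemokinePanel:
    """Load the CI panel from ``path`` or from the packaged dataset."""
    return ChemokinePanel.from_csv(path or default_dataset_path(), **kwargs)
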