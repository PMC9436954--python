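"""Drug-label reference standard: Y / N / U classification of drug-AE pairs.

The training labels for supervised signal detection come from regulatory
drug labels.  For a study drug and the other drugs of its therapeutic
class, a *label history* records the first year each AE term was listed.
Every drug-AE pair observed in a report universe is then classified, as of
a given year:

* ``Y`` (label-positive): the AE is on the study drug's label by that year;
* ``N`` (label-negative): the AE is on no label — neither the study drug's
  nor any same-class drug's — by that year;
* ``U`` (unknown): everything else, e.g. an AE listed only for a class
  drug.  U pairs are the screening pool in which new signals are sought.

Boundary convention: an AE whose label year equals the query year counts
as labeled, so "detected before the label update" means strictly
``detection_year < label_year``.

Term matching is exact string equality after case-folding and whitespace
trimming; mapping between coding dictionaries is upstream curation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import ReportSet, observed_terms

logger = logging.getLogger("pvsignal")

__all__ = [
    "LabelHistory",
    "PairClassification",
    "classify_pairs",
    "classification_map",
    "reference_standard_series",
]

LABEL_CLASSES = ("Y", "N", "U")


def _fold(term: str) -> str:
    return str(term).strip().casefold()


@dataclass(frozen=True)
class LabelHistory:
    """Per-drug first-listing years of AE terms.

    ``entries`` maps ``(drug_id, ae_term)`` (both case-folded) to the first
    calendar year the term appeared on that drug's label.
    """

    entries: Mapping[tuple[str, str], int]

    @classmethod
    def from_entries(
        cls, triples: Iterable[tuple[str, str, int]]
    ) -> "LabelHistory":
        """Build from ``(drug_id, ae_term, label_year)`` triples.

        Repeated pairs keep the earliest year (first listing).
        """
        out: dict[tuple[str, str], int] = {}
        for drug, term, year in triples:
            key = (_fold(drug), _fold(term))
            year = int(year)
            if key not in out or year < out[key]:
                out[key] = year
        return cls(entries=out)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelHistory":
        """Read a label-history CSV with columns drug_id, ae_term, label_year."""
        frame_rows: list[tuple[str, str, int]] = []
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle)
            missing = [
                c for c in ("drug_id", "ae_term", "label_year")
                if c not in (reader.fieldnames or [])
            ]
            if missing:
                raise ValueError(f"label history CSV missing column(s): {missing}")
            for row in reader:
                frame_rows.append(
                    (row["drug_id"], row["ae_term"], int(row["label_year"]))
                )
        return cls.from_entries(frame_rows)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["drug_id", "ae_term", "label_year"])
            for (drug, term), year in sorted(self.entries.items()):
                writer.writerow([drug, term, year])

    def label_year(self, drug: str, ae_term: str) -> int | None:
        return self.entries.get((_fold(drug), _fold(ae_term)))

    def drugs(self) -> list[str]:
        return sorted({drug for drug, _ in self.entries})

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PairClassification:
    drug_id: str
    ae_term: str
    as_of_year: int
    label_class: str

    def __post_init__(self) -> None:
        if self.label_class not in LABEL_CLASSES:
            raise ValueError(f"label_class must be one of {LABEL_CLASSES}")


def classify_pairs(
    rs: ReportSet,
    lh: LabelHistory,
    study_drug: str,
    class_drugs: Sequence[str],
    as_of_year: int,
) -> list[PairClassification]:
    """Classify every AE term observed in ``rs`` against the study drug.

    ``Y`` iff the study drug's label lists the term with label year
    <= ``as_of_year``; ``N`` iff no label (study drug nor any class drug)
    lists it by then; ``U`` otherwise.
    """
    if not class_drugs:
        raise ValueError("class_drugs must be non-empty")
    if rs.year_range is not None and as_of_year < rs.year_range[0]:
        raise ValueError(
            f"as_of_year {as_of_year} precedes study window start {rs.year_range[0]}"
        )
    out = []
    for term in observed_terms(rs):
        study_year = lh.label_year(study_drug, term)
        if study_year is not None and study_year <= as_of_year:
            cls = "Y"
        else:
            # a future study-drug listing is invisible as of this year
            class_listed = any(
                (year := lh.label_year(drug, term)) is not None and year <= as_of_year
                for drug in class_drugs
            )
            cls = "U" if class_listed else "N"
        out.append(
            PairClassification(
                drug_id=study_drug, ae_term=term,
                as_of_year=as_of_year, label_class=cls,
            )
        )
    return out


def classification_map(
    classifications: Iterable[PairClassification],
) -> dict[str, str]:
    """``{ae_term: label_class}`` convenience view."""
    return {c.ae_term: c.label_class for c in classifications}


def reference_standard_series(
    lh: LabelHistory,
    cumulative_sets: Sequence[ReportSet],
    study_drug: str,
    class_drugs: Sequence[str],
) -> dict[int, list[PairClassification]]:
    """Year-indexed classifications over nested cumulative datasets.

    Each cumulative set is classified as of its own final year, so an AE
    labeled in year L is U (or N) before L and Y from L onward.
    """
    series: dict[int, list[PairClassification]] = {}
    for cum in cumulative_sets:
        if cum.year_range is None:
            raise ValueError("cumulative sets must carry a year_range")
        year = cum.year_range[1]
        series[year] = classify_pairs(cum, lh, study_drug, class_drugs, year)
    return series
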