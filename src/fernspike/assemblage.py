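"""Quantification of palynological assemblages.

Turns raw microscope counts into the three quantities that characterise a
terrestrial disturbance signal in marine-margin palynology:

* **relative abundance** of ecological groups, as a percentage of the total
  terrestrial pollen-and-spore assemblage (marine palynomorphs and the exotic
  marker excluded from numerator and denominator);
* **absolute concentration** in grains per gram of dry sediment, obtained by
  normalising counts against a spiked exotic marker (*Lycopodium*) of known
  abundance;
* **microcharcoal fraction** as a percentage of the total palynofacies, a
  wildfire-activity proxy.

Fold changes between depth intervals (e.g. the ~70-fold fern-spore increase
across a carbon-isotope-excursion base) are computed from interval means of
the spike-normalised concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

__all__ = [
    "UndefinedQuantityError",
    "PalynoSample",
    "TaxonGroupMap",
    "CharcoalFraction",
    "default_group_map",
    "relative_abundance",
    "concentration",
    "microcharcoal_fraction",
    "fold_change",
    "assemblage_table",
    "write_counts_csv",
    "read_counts_csv",
    "round_sig",
]

#: Ecological groups used throughout; "fern" carries the Gleicheniaceae
#: sub-flag via :attr:`TaxonGroupMap.gleicheniaceae_taxa`.
TERRESTRIAL_GROUPS = ("fern", "angiosperm", "cupressaceae", "pinaceae", "other_terrestrial")
MARKER_GROUP = "marker"
MARINE_GROUP = "marine"


class UndefinedQuantityError(ValueError):
    """A requested quantity is undefined for this sample (e.g. zero
    terrestrial total, or no marker grains counted). Raised instead of
    silently propagating NaN."""


@dataclass
class PalynoSample:
    """Raw counts for one depth horizon.

    Parameters
    ----------
    depth_mbsf
        Sample depth in meters below sea floor (positive downward).
    taxon_counts
        Mapping taxon name -> non-negative integer count. Marker grains are
        *not* part of this mapping; they are recorded in ``lyco_counted``.
    lyco_counted, lyco_spiked
        Exotic *Lycopodium* marker grains counted on the slide, and the known
        number of marker grains added to the sample during processing.
    dry_weight_g
        Dry sediment weight processed, in grams.
    palynofacies_counts
        Mapping palynofacies category -> count; the ``"microcharcoal"``
        category feeds the wildfire proxy.
    tephra_flag
        True for samples inside volcanic ash layers (zero biogenic content).
    h_m
        Height above the CIE base in meters (positive upsection); filled in
        by :func:`fernspike.chronology.align_to_cie`.
    """

    depth_mbsf: float
    taxon_counts: dict[str, int]
    lyco_counted: int
    lyco_spiked: int
    dry_weight_g: float
    palynofacies_counts: dict[str, int] = field(default_factory=dict)
    tephra_flag: bool = False
    h_m: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.depth_mbsf):
            raise ValueError("depth_mbsf must be finite")
        if self.dry_weight_g <= 0:
            raise ValueError(f"dry_weight_g must be > 0, got {self.dry_weight_g}")
        if self.lyco_spiked <= 0:
            raise ValueError(f"lyco_spiked must be > 0, got {self.lyco_spiked}")
        if self.lyco_counted < 0:
            raise ValueError("lyco_counted must be >= 0")
        for name, count in self.taxon_counts.items():
            if not name:
                raise ValueError("taxon names must be non-empty")
            if count < 0:
                raise ValueError(f"negative count for taxon {name!r}")
        for name, count in self.palynofacies_counts.items():
            if count < 0:
                raise ValueError(f"negative palynofacies count for {name!r}")


@dataclass(frozen=True)
class TaxonGroupMap:
    """Configuration mapping each taxon to exactly one ecological group.

    Groups are flagged terrestrial or not; the marker group never enters any
    assemblage sum. Gleicheniaceae membership is carried as a sub-flag on the
    fern group so fire-adapted ferns can be reported separately.
    """

    taxon_to_group: Mapping[str, str]
    terrestrial_groups: tuple[str, ...] = TERRESTRIAL_GROUPS
    marker_group: str = MARKER_GROUP
    marine_groups: tuple[str, ...] = (MARINE_GROUP,)
    gleicheniaceae_taxa: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        known = set(self.terrestrial_groups) | set(self.marine_groups) | {self.marker_group}
        for taxon, group in self.taxon_to_group.items():
            if group not in known:
                raise ValueError(f"taxon {taxon!r} maps to unknown group {group!r}")

    def group_of(self, taxon: str) -> str:
        try:
            return self.taxon_to_group[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} missing from group map") from None

    def is_terrestrial(self, group: str) -> bool:
        return group in self.terrestrial_groups

    def taxa_of(self, group: str, sample: PalynoSample) -> list[str]:
        """Taxa of *group* present in the sample's count table."""
        return [t for t in sample.taxon_counts if self.taxon_to_group.get(t) == group]

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "taxon_to_group": dict(self.taxon_to_group),
            "terrestrial_groups": list(self.terrestrial_groups),
            "marker_group": self.marker_group,
            "marine_groups": list(self.marine_groups),
            "gleicheniaceae_taxa": sorted(self.gleicheniaceae_taxa),
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaxonGroupMap":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            taxon_to_group=payload["taxon_to_group"],
            terrestrial_groups=tuple(payload["terrestrial_groups"]),
            marker_group=payload["marker_group"],
            marine_groups=tuple(payload["marine_groups"]),
            gleicheniaceae_taxa=frozenset(payload.get("gleicheniaceae_taxa", ())),
        )


def default_group_map() -> TaxonGroupMap:
    """Group map for the taxa emitted by :mod:`fernspike.synthetic`, modelled
    on a conifer-swamp / fern-spike / broad-leaved-forest succession."""
    mapping = {
        "Gleicheniaceae": "fern",
        "other_fern_spores": "fern",
        "Alnipollenites": "angiosperm",
        "Ulmipollenites": "angiosperm",
        "Cupressaceae_pollen": "cupressaceae",
        "Pinaceae_pollen": "pinaceae",
        "other_terrestrial_palynomorphs": "other_terrestrial",
        "dinocysts": "marine",
        "Lycopodium_marker": "marker",
    }
    return TaxonGroupMap(taxon_to_group=mapping, gleicheniaceae_taxa=frozenset({"Gleicheniaceae"}))


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def _terrestrial_total(sample: PalynoSample, groups: TaxonGroupMap) -> int:
    return sum(
        c
        for t, c in sample.taxon_counts.items()
        if groups.is_terrestrial(groups.group_of(t))
    )


def relative_abundance(sample: PalynoSample, groups: TaxonGroupMap) -> dict[str, float]:
    """Percent of the total terrestrial pollen-and-spore assemblage per group.

    Marine taxa and the exotic marker are excluded from both numerator and
    denominator. The returned percentages sum to 100 exactly (up to float
    round-off).

    Raises
    ------
    UndefinedQuantityError
        If the sample contains no terrestrial grains (e.g. a tephra sample);
        the message carries the sample depth.
    """
    total = _terrestrial_total(sample, groups)
    if total == 0:
        raise UndefinedQuantityError(
            f"relative abundance undefined: zero terrestrial pollen+spore count "
            f"at depth {sample.depth_mbsf} mbsf"
        )
    out = {g: 0.0 for g in groups.terrestrial_groups}
    for taxon, count in sample.taxon_counts.items():
        group = groups.group_of(taxon)
        if groups.is_terrestrial(group):
            out[group] += 100.0 * count / total
    return out


def _selected_count(sample: PalynoSample, selector: str, groups: TaxonGroupMap | None) -> int:
    """Resolve *selector* (a taxon name, a group name, or "total_terrestrial")
    to a summed count."""
    if selector in sample.taxon_counts:
        return sample.taxon_counts[selector]
    if groups is not None:
        if selector == "total_terrestrial":
            return _terrestrial_total(sample, groups)
        group_names = set(groups.terrestrial_groups) | set(groups.marine_groups)
        if selector in group_names:
            return sum(
                c for t, c in sample.taxon_counts.items()
                if groups.taxon_to_group.get(t) == selector
            )
    raise KeyError(
        f"selector {selector!r} is neither a taxon of this sample nor a known group"
    )


def concentration(
    sample: PalynoSample, selector: str, groups: TaxonGroupMap | None = None
) -> float:
    """Spike-normalised absolute concentration, grains per g dry sediment.

    ``conc = count(selector) * lyco_spiked / (lyco_counted * dry_weight)``

    *selector* may be a taxon name, a group name (requires *groups*), or
    ``"total_terrestrial"``.

    Raises
    ------
    UndefinedQuantityError
        If no marker grains were counted (normalisation impossible).
    """
    if sample.lyco_counted == 0:
        raise UndefinedQuantityError(
            f"concentration undefined: no marker grains counted at depth "
            f"{sample.depth_mbsf} mbsf"
        )
    count = _selected_count(sample, selector, groups)
    return count * sample.lyco_spiked / (sample.lyco_counted * sample.dry_weight_g)


class CharcoalFraction(NamedTuple):
    """Microcharcoal as % of total palynofacies; ``absent`` marks samples
    where no microcharcoal was observed (the "x" convention)."""

    percent: float
    absent: bool


def microcharcoal_fraction(sample: PalynoSample) -> CharcoalFraction:
    """Microcharcoal particles as a percentage of the total palynofacies."""
    total = sum(sample.palynofacies_counts.values())
    if total == 0:
        raise UndefinedQuantityError(
            f"microcharcoal fraction undefined: empty palynofacies table at "
            f"depth {sample.depth_mbsf} mbsf"
        )
    charcoal = sample.palynofacies_counts.get("microcharcoal", 0)
    return CharcoalFraction(percent=100.0 * charcoal / total, absent=charcoal == 0)


def _interval_samples(
    samples: Iterable[PalynoSample],
    interval: tuple[float, float],
    include_tephra: bool,
) -> list[PalynoSample]:
    lo, hi = sorted(interval)
    out = [s for s in samples if lo <= s.depth_mbsf <= hi]
    if not include_tephra:
        out = [s for s in out if not s.tephra_flag]
    return out


def fold_change(
    record,
    selector: str,
    pre_interval: tuple[float, float],
    post_interval: tuple[float, float],
    groups: TaxonGroupMap | None = None,
    include_tephra: bool = False,
) -> float:
    """Ratio of mean concentrations (post-interval / pre-interval).

    *record* is a :class:`fernspike.chronology.SiteRecord` or any iterable of
    :class:`PalynoSample`. Intervals are (depth, depth) pairs in mbsf; the
    "post" interval is the stratigraphically younger (shallower) one.
    Tephra-flagged samples are excluded by default.

    Raises
    ------
    UndefinedQuantityError
        If either interval holds no usable sample, or the pre-interval mean
        concentration is zero (ratio undefined/infinite).
    """
    samples = getattr(record, "samples", record)
    pre = _interval_samples(samples, pre_interval, include_tephra)
    post = _interval_samples(samples, post_interval, include_tephra)
    if not pre or not post:
        raise UndefinedQuantityError(
            f"fold change needs >=1 non-tephra sample in each interval "
            f"(pre: {len(pre)}, post: {len(post)})"
        )
    pre_mean = sum(concentration(s, selector, groups) for s in pre) / len(pre)
    post_mean = sum(concentration(s, selector, groups) for s in post) / len(post)
    if pre_mean == 0:
        raise UndefinedQuantityError(
            f"fold change undefined: zero mean pre-interval concentration for "
            f"{selector!r}"
        )
    return post_mean / pre_mean


# ---------------------------------------------------------------------------
# Tidy output & CSV interfaces
# ---------------------------------------------------------------------------

def assemblage_table(record, groups: TaxonGroupMap) -> pd.DataFrame:
    """Tidy per-sample/per-group table: ``depth_mbsf, group, percent,
    concentration_per_g``. Tephra samples yield NaN rows (quantities
    undefined there) so the depth series stays complete."""
    samples = getattr(record, "samples", record)
    rows = []
    for s in samples:
        try:
            pct = relative_abundance(s, groups)
        except UndefinedQuantityError:
            pct = {g: float("nan") for g in groups.terrestrial_groups}
        for g in groups.terrestrial_groups:
            try:
                conc = concentration(s, g, groups)
            except (UndefinedQuantityError, KeyError):
                conc = float("nan")
            rows.append(
                {
                    "depth_mbsf": s.depth_mbsf,
                    "group": g,
                    "percent": pct[g],
                    "concentration_per_g": conc,
                }
            )
    return pd.DataFrame(rows)


def round_sig(x: float, digits: int = 4) -> float:
    """Presentation rounding to *digits* significant digits (export only;
    nothing is rounded internally)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def write_counts_csv(
    samples: Sequence[PalynoSample],
    counts_path: str | Path,
    palynofacies_path: str | Path | None = None,
) -> None:
    """Write the counts table (one row per sample): ``depth_mbsf,
    dry_weight_g, lyco_counted, lyco_spiked, tephra, <taxon columns...>``;
    optionally a parallel palynofacies table."""
    taxa = sorted({t for s in samples for t in s.taxon_counts})
    rows = []
    for s in samples:
        row = {
            "depth_mbsf": s.depth_mbsf,
            "dry_weight_g": s.dry_weight_g,
            "lyco_counted": s.lyco_counted,
            "lyco_spiked": s.lyco_spiked,
            "tephra": int(s.tephra_flag),
        }
        row.update({t: s.taxon_counts.get(t, 0) for t in taxa})
        rows.append(row)
    pd.DataFrame(rows).to_csv(counts_path, index=False)

    if palynofacies_path is not None:
        cats = sorted({c for s in samples for c in s.palynofacies_counts})
        prows = []
        for s in samples:
            prow = {"depth_mbsf": s.depth_mbsf}
            prow.update({c: s.palynofacies_counts.get(c, 0) for c in cats})
            prows.append(prow)
        pd.DataFrame(prows).to_csv(palynofacies_path, index=False)


_META_COLUMNS = ("depth_mbsf", "dry_weight_g", "lyco_counted", "lyco_spiked", "tephra")


def read_counts_csv(
    counts_path: str | Path,
    palynofacies_path: str | Path | None = None,
) -> list[PalynoSample]:
    """Inverse of :func:`write_counts_csv`."""
    df = pd.read_csv(counts_path)
    taxa = [c for c in df.columns if c not in _META_COLUMNS]
    pf_by_depth: dict[float, dict[str, int]] = {}
    if palynofacies_path is not None:
        pf = pd.read_csv(palynofacies_path)
        cats = [c for c in pf.columns if c != "depth_mbsf"]
        for _, row in pf.iterrows():
            pf_by_depth[float(row["depth_mbsf"])] = {c: int(row[c]) for c in cats}
    samples = []
    for _, row in df.iterrows():
        depth = float(row["depth_mbsf"])
        samples.append(
            PalynoSample(
                depth_mbsf=depth,
                taxon_counts={t: int(row[t]) for t in taxa},
                lyco_counted=int(row["lyco_counted"]),
                lyco_spiked=int(row["lyco_spiked"]),
                dry_weight_g=float(row["dry_weight_g"]),
                palynofacies_counts=pf_by_depth.get(depth, {}),
                tephra_flag=bool(row["tephra"]),
            )
        )
    return samples
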