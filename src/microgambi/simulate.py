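"""Synthetic taxa references and read-count tables with known composition.

The generator builds a miniature curated list (EGI / EGIII / not-assigned
taxa with field-style "GenusNNN speciesNNN" names) and, per station, draws a
single multinomial of ``total_reads_per_station`` reads over all taxa.  The
expected allocation gives the not-assigned and not-in-list taxa their
configured read shares and splits the remaining (assigned) share between
EGIII and EGI as pi : 1-pi, where pi is the station's tolerant-read
fraction — the ground-truth parameter that the index should recover:

    E[microgAMBI] ~= weight_egi + (weight_egiii - weight_egi) * pi

Within each ecological group, reads spread uniformly over the group's taxa,
or with symmetric-Dirichlet weights when ``dispersion`` > 0 (larger values
give burstier, less even communities; 0 reproduces the exact multinomial
expectation).  The model is deliberately minimal: it makes no attempt at
real 16S compositional structure (phylogenetic correlation, zero-inflation
calibration), so it validates the arithmetic of the pipeline, not its
behaviour on real amplicon data.

A deliberate fraction of genus-level reference taxa appear in the count
table with a trailing " sp.", exercising the name-normalization path end to
end.  Seeded generation is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .community import AbundanceMatrix
from .index import IndexConfig
from .taxa import EcologicalGroup, TaxaReference, TaxonRecord

__all__ = ["CommunitySpec", "generate_reference", "generate_communities",
           "expected_index"]


@dataclass
class CommunitySpec:
    """Parameters of one synthetic study.

    ``egiii_read_fraction_per_station`` (pi, one value per station) is the
    expected fraction of *assigned* reads carried by tolerant (EGIII) taxa;
    ``None`` spreads the stations evenly over [0, 1], covering the whole
    status gradient.  ``not_assigned_read_share`` / ``not_in_list_read_share``
    are the expected fractions of the station total going to uncategorized
    and unlisted taxa (small by default — a well-covered survey).
    """

    n_stations: int = 5
    egiii_read_fraction_per_station: Optional[Sequence[float]] = None
    n_taxa_egi: int = 40
    n_taxa_egiii: int = 40
    n_taxa_not_assigned: int = 5
    n_taxa_not_in_list: int = 5
    total_reads_per_station: int = 10_000
    not_assigned_read_share: float = 0.02
    not_in_list_read_share: float = 0.03
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_stations", "n_taxa_egi", "n_taxa_egiii",
                     "n_taxa_not_assigned", "n_taxa_not_in_list",
                     "total_reads_per_station"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_stations < 1:
            raise ValueError("need at least one station")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for s in (self.not_assigned_read_share, self.not_in_list_read_share):
            if not 0 <= s <= 1:
                raise ValueError("read shares must lie in [0, 1]")
        if self.not_assigned_read_share + self.not_in_list_read_share > 1:
            raise ValueError("unmatched read shares exceed the whole")
        if self.egiii_read_fraction_per_station is None:
            if self.n_stations == 1:
                pis = (0.5,)
            else:
                pis = tuple(np.linspace(0.0, 1.0, self.n_stations))
        else:
            pis = tuple(float(x) for x in self.egiii_read_fraction_per_station)
        if len(pis) != self.n_stations:
            raise ValueError(
                "egiii_read_fraction_per_station length must equal n_stations"
            )
        if any(not 0 <= p <= 1 for p in pis):
            raise ValueError("EGIII read fractions must lie in [0, 1]")
        self.egiii_read_fraction_per_station = pis


def _names(prefix: str, epithet: str, n: int, genus_only_every: int = 5) -> list[str]:
    """Synthetic binomials; every ``genus_only_every``-th entry is genus-level."""
    out = []
    for i in range(1, n + 1):
        if genus_only_every and i % genus_only_every == 0:
            out.append(f"{prefix}{i:03d}")
        else:
            out.append(f"{prefix}{i:03d} {epithet}{i:03d}")
    return out


def _group_names(spec: CommunitySpec) -> dict[EcologicalGroup, list[str]]:
    return {
        EcologicalGroup.EGI: _names("Sensigenus", "aequoris", spec.n_taxa_egi),
        EcologicalGroup.EGIII: _names("Tolerigenus", "limicola", spec.n_taxa_egiii),
        EcologicalGroup.NOT_ASSIGNED: _names("Incognigenus", "dubius",
                                             spec.n_taxa_not_assigned),
    }


def _unlisted_names(spec: CommunitySpec) -> list[str]:
    return _names("Ignotigenus", "absens", spec.n_taxa_not_in_list)


def generate_reference(spec: CommunitySpec) -> TaxaReference:
    """Synthesize a miniature curated list matching the spec's group sizes.

    Not-in-list taxa are generated by :func:`generate_communities` but
    deliberately omitted here.  The output passes reference validation with
    zero issues.
    """
    records: list[TaxonRecord] = []
    lookup_map: dict[str, TaxonRecord] = {}
    n = 0
    for eg, names in _group_names(spec).items():
        for name in names:
            n += 1
            rec = TaxonRecord(
                row_number=n, name=name, eg=eg,
                literature="synthetic fixture",
                comments="generated taxon; no biological meaning",
            )
            records.append(rec)
            lookup_map[name.casefold()] = rec
    return TaxaReference(records=records, lookup_map=lookup_map,
                         version_label=f"synthetic-seed{spec.seed}")


def _row_labels(spec: CommunitySpec) -> list[str]:
    """Count-table row labels: reference names plus unlisted taxa; genus-level
    entries carry a trailing ' sp.' as classifier outputs commonly do."""
    labels = []
    groups = _group_names(spec)
    for names in groups.values():
        for name in names:
            labels.append(name if " " in name else name + " sp.")
    labels.extend(_unlisted_names(spec))
    return labels


def generate_communities(ref: TaxaReference, spec: CommunitySpec) -> AbundanceMatrix:
    """Draw per-station multinomial read counts with the spec's composition.

    Column sums equal ``total_reads_per_station`` exactly.  Raises when the
    reference does not match the spec (it must come from
    :func:`generate_reference` with the same group sizes).
    """
    expected = generate_reference(spec)
    if [r.name for r in ref.records] != [r.name for r in expected.records] or [
        r.eg for r in ref.records
    ] != [r.eg for r in expected.records]:
        raise ValueError("reference does not match the community spec")

    rng = np.random.default_rng(spec.seed)
    groups = _group_names(spec)
    sizes = {eg: len(names) for eg, names in groups.items()}
    n_unlisted = spec.n_taxa_not_in_list
    labels = _row_labels(spec)
    n_rows = len(labels)

    s_na = spec.not_assigned_read_share if sizes[EcologicalGroup.NOT_ASSIGNED] else 0.0
    s_nil = spec.not_in_list_read_share if n_unlisted else 0.0
    s_assigned = 1.0 - s_na - s_nil

    counts = np.zeros((n_rows, spec.n_stations), dtype=np.int64)
    for j, pi in enumerate(spec.egiii_read_fraction_per_station):
        shares = [
            s_assigned * (1.0 - pi),   # EGI block
            s_assigned * pi,           # EGIII block
            s_na,                      # not assigned block
            s_nil,                     # not in list block
        ]
        blocks = [sizes[EcologicalGroup.EGI], sizes[EcologicalGroup.EGIII],
                  sizes[EcologicalGroup.NOT_ASSIGNED], n_unlisted]
        # rows are laid out block-wise (EGI, EGIII, not-assigned, unlisted);
        # zero-sized blocks contribute no rows, so the offset only advances
        # for populated blocks
        p = np.zeros(n_rows)
        start = 0
        for share, k in zip(shares, blocks):
            if k == 0:
                if share > 0:
                    raise ValueError(
                        "spec allocates reads to a group with zero taxa"
                    )
                continue
            if spec.dispersion > 0:
                w = rng.dirichlet(np.full(k, 1.0 / spec.dispersion))
            else:
                w = np.full(k, 1.0 / k)
            p[start:start + k] = share * w
            start += k
        total = p.sum()
        if total == 0:
            raise ValueError("spec allocates no reads to any taxon")
        p = p / total
        counts[:, j] = rng.multinomial(spec.total_reads_per_station, p)

    return AbundanceMatrix(
        taxa_names=labels,
        station_ids=[f"ST{j + 1:02d}" for j in range(spec.n_stations)],
        counts=counts,
    )


def expected_index(pi: float, cfg: IndexConfig | None = None) -> float:
    """Analytic expectation of the index for a tolerant-read fraction pi.

    Linear interpolation between the two weights; the oracle for
    parameter-recovery checks.
    """
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    cfg = cfg or IndexConfig()
    return cfg.weight_egi + (cfg.weight_egiii - cfg.weight_egi) * pi
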