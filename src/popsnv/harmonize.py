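"""Reference-panel harmonization: one assembly, one rsID per site.

An older-assembly panel (HapMap-style) is brought onto the target
assembly in four steps: drop non-SNV sites and sites whose rsID maps to
more than one position; convert coordinates through a precomputed
position map; rescue conversion failures by unique rsID match against a
panel already on the target assembly; and finally enforce a single rsID
per position across all datasets, choosing the survivor with a seeded
generator so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .model import CoordinateMap, GenomicPosition, PanelDataset, PanelSite

logger = logging.getLogger(__name__)


@dataclass
class RemovedSite:
    site: PanelSite
    reason: str


def remove_invalid_sites(panel: PanelDataset) -> tuple:
    """Drop non-SNV sites and sites with a non-unique rsID.

    Returns ``(cleaned_panel, removed)`` where each removal records its
    reason (``not_snv`` or ``non_unique_rsid``). A single-position SNV
    site is never removed.
    """
    bad_rsids = {r for r, positions in panel.rsid_index.items() if len(positions) > 1}
    cleaned = PanelDataset(name=panel.name, assembly=panel.assembly)
    removed = []
    for pos in sorted(panel.sites, key=lambda p: p.sort_key()):
        site = panel.sites[pos]
        if not site.is_snv:
            removed.append(RemovedSite(site, "not_snv"))
        elif site.rsid in bad_rsids:
            removed.append(RemovedSite(site, "non_unique_rsid"))
        else:
            cleaned.add_site(site)
    if removed:
        logger.info(
            "%s: removed %d invalid sites (%d non-SNV, %d non-unique rsID)",
            panel.name,
            len(removed),
            sum(r.reason == "not_snv" for r in removed),
            sum(r.reason == "non_unique_rsid" for r in removed),
        )
    return cleaned, removed


def liftover_sites(panel: PanelDataset, cmap: CoordinateMap, new_assembly: str = "new") -> tuple:
    """Re-key panel sites through an old→new coordinate map.

    Returns ``(converted_panel, failed_sites)``; sites absent from the
    map are conversion failures. Two old positions mapping onto one new
    position is a validation error (the map itself forbids it, but a
    site already at the target position triggers it too).
    """
    converted = PanelDataset(name=panel.name, assembly=new_assembly)
    failed = []
    for pos in sorted(panel.sites, key=lambda p: p.sort_key()):
        site = panel.sites[pos]
        new_pos = cmap.get(pos)
        if new_pos is None:
            failed.append(site)
            continue
        converted.add_site(
            PanelSite(
                position=new_pos,
                rsid=site.rsid,
                ref=site.ref,
                alts=site.alts,
                assembly=new_assembly,
                is_snv=site.is_snv,
            )
        )
    return converted, failed


def rescue_failed_by_rsid(failed: list, reference_panel: PanelDataset) -> tuple:
    """Assign target-assembly positions to conversion failures by rsID.

    A failed site is rescued when its rsID occurs at exactly one
    position of ``reference_panel``; anything else (absent, ambiguous,
    no rsID, position already taken) is lost.
    """
    rescued = PanelDataset(name="rescued", assembly=reference_panel.assembly)
    lost = []
    for site in failed:
        if site.rsid is None:
            lost.append(site)
            continue
        positions = reference_panel.rsid_positions(site.rsid)
        if len(positions) != 1:
            if len(positions) > 1:
                logger.warning(
                    "rsID %s ambiguous in %s (%d positions); dropping",
                    site.rsid, reference_panel.name, len(positions),
                )
            lost.append(site)
            continue
        (new_pos,) = positions
        if new_pos in rescued:
            lost.append(site)
            continue
        rescued.add_site(
            PanelSite(
                position=new_pos,
                rsid=site.rsid,
                ref=site.ref,
                alts=site.alts,
                assembly=reference_panel.assembly,
                is_snv=site.is_snv,
            )
        )
    return rescued, lost


def merge_panels(name: str, *panels: PanelDataset) -> PanelDataset:
    """Union of same-assembly panels; first occurrence wins per position."""
    assemblies = {p.assembly for p in panels}
    if len(assemblies) != 1:
        raise ValueError(f"cannot merge panels across assemblies {sorted(assemblies)}")
    out = PanelDataset(name=name, assembly=assemblies.pop())
    for p in panels:
        for pos in sorted(p.sites, key=lambda q: q.sort_key()):
            if pos not in out:
                out.add_site(p.sites[pos])
    return out


def dedup_rsids(datasets: dict, seed: int) -> dict:
    """Enforce one rsID per position, consistently across datasets.

    ``datasets`` maps name → either a :class:`PanelDataset` or an object
    with a ``sites`` DataFrame carrying an ``rsid`` column of
    comma-separated identifiers. For every position that carries two or
    more distinct rsIDs (within or across datasets), one survivor is
    chosen uniformly at random (seeded) and applied everywhere; the other
    identifiers are discarded.
    """
    rng = np.random.default_rng(seed)
    by_position: dict = {}

    def _collect(pos: GenomicPosition, rsid: Optional[str]):
        if rsid:
            for r in rsid.split(","):
                if r and r != ".":
                    by_position.setdefault(pos, set()).add(r)

    for ds in datasets.values():
        if isinstance(ds, PanelDataset):
            for pos, site in ds.sites.items():
                _collect(pos, site.rsid)
        else:  # ConsensusSet-like: sites DataFrame with optional rsid column
            if "rsid" in ds.sites.columns:
                for c, p, r in zip(ds.sites["chrom"], ds.sites["pos"], ds.sites["rsid"]):
                    _collect(GenomicPosition(c, p), r)

    survivor = {}
    n_multi = 0
    for pos in sorted(by_position, key=lambda p: p.sort_key()):
        rsids = sorted(by_position[pos])
        if len(rsids) == 1:
            survivor[pos] = rsids[0]
        else:
            n_multi += 1
            survivor[pos] = rsids[int(rng.integers(len(rsids)))]
    if n_multi:
        logger.info("resolved %d multi-rsID positions (seed=%d)", n_multi, seed)

    out = {}
    for name, ds in datasets.items():
        if isinstance(ds, PanelDataset):
            cleaned = PanelDataset(name=ds.name, assembly=ds.assembly)
            for pos in sorted(ds.sites, key=lambda q: q.sort_key()):
                site = ds.sites[pos]
                cleaned.add_site(
                    PanelSite(
                        position=site.position,
                        rsid=survivor.get(pos, site.rsid),
                        ref=site.ref,
                        alts=site.alts,
                        assembly=site.assembly,
                        is_snv=site.is_snv,
                    )
                )
            out[name] = cleaned
        else:
            ds = ds  # in-place annotation of the sites table copy
            if "rsid" in ds.sites.columns:
                new_rsids = [
                    survivor.get(GenomicPosition(c, p), r)
                    for c, p, r in zip(ds.sites["chrom"], ds.sites["pos"], ds.sites["rsid"])
                ]
                ds.sites = ds.sites.assign(rsid=new_rsids)
            out[name] = ds
    return out
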