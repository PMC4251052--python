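import numpy as np
import pytest

from popsnv.harmonize import (
    dedup_rsids,
    liftover_sites,
    merge_panels,
    remove_invalid_sites,
    rescue_failed_by_rsid,
)
from popsnv.model import CoordinateMap, GenomicPosition, PanelDataset, PanelSite


def site(chrom, pos, rsid=None, ref="A", alts=("G",), assembly="old", is_snv=True):
    return PanelSite(position=GenomicPosition(chrom, pos), rsid=rsid, ref=ref,
                     alts=alts, assembly=assembly, is_snv=is_snv)


def panel(sites, name="p", assembly="old"):
    return PanelDataset(name=name, assembly=assembly, sites=sites)


class TestRemoveInvalid:
    def test_non_unique_rsid_removed_everywhere(self):
        p = panel([site("1", 100, rsid="rsX"), site("2", 300, rsid="rsX"),
                   site("1", 500, rsid="rs1")])
        cleaned, removed = remove_invalid_sites(p)
        assert cleaned.positions() == {GenomicPosition("1", 500)}
        assert {r.reason for r in removed} == {"non_unique_rsid"}

    def test_indel_removed(self):
        p = panel([site("1", 100, rsid="rs1", ref="AT", is_snv=False),
                   site("1", 200, rsid="rs2")])
        cleaned, removed = remove_invalid_sites(p)
        assert len(cleaned) == 1
        assert removed[0].reason == "not_snv"

    def test_clean_panel_is_identity(self):
        p = panel([site("1", i * 10, rsid=f"rs{i}") for i in range(1, 6)])
        cleaned, removed = remove_invalid_sites(p)
        assert cleaned.positions() == p.positions() and removed == []


class TestLiftover:
    def test_mapped_site_rekeyed(self):
        cmap = CoordinateMap([(GenomicPosition("1", 100), GenomicPosition("1", 150))])
        converted, failed = liftover_sites(panel([site("1", 100, rsid="rs1")]), cmap)
        assert converted.positions() == {GenomicPosition("1", 150)}
        assert converted.assembly == "new" and failed == []

    def test_unmapped_site_fails(self):
        converted, failed = liftover_sites(panel([site("1", 100)]), CoordinateMap())
        assert len(converted) == 0 and len(failed) == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        positions = sorted(rng.choice(10_000, size=10, replace=False) + 1)
        sites = [site("1", int(p), rsid=f"rs{i}") for i, p in enumerate(positions)]
        mapped = positions[:7]
        cmap = CoordinateMap(
            [(GenomicPosition("1", int(p)), GenomicPosition("1", int(p) + 37))
             for p in mapped]
        )
        converted, failed = liftover_sites(panel(sites), cmap)
        assert len(converted) == 7 and len(failed) == 3
        assert len(converted) + len(failed) == len(sites)


class TestRescue:
    def reference(self):
        return panel([site("5", 500, rsid="rs123", assembly="new")],
                     name="ref", assembly="new")

    def test_unique_rsid_rescued(self):
        rescued, lost = rescue_failed_by_rsid([site("1", 100, rsid="rs123")],
                                              self.reference())
        assert rescued.positions() == {GenomicPosition("5", 500)} and lost == []

    def test_absent_rsid_lost(self):
        rescued, lost = rescue_failed_by_rsid([site("1", 100, rsid="rs999")],
                                              self.reference())
        assert len(rescued) == 0 and len(lost) == 1

    def test_ambiguous_rsid_lost(self):
        ref = panel([site("5", 500, rsid="rs7", assembly="new"),
                     site("6", 600, rsid="rs7", assembly="new")],
                    name="ref", assembly="new")
        rescued, lost = rescue_failed_by_rsid([site("1", 100, rsid="rs7")], ref)
        assert len(rescued) == 0 and len(lost) == 1

    def test_liftover_rescue_conservation(self):
        """|converted| + |rescued| + |lost| equals the post-removal panel size."""
        sites = [site("1", p, rsid=f"rs{p}") for p in (10, 20, 30, 40, 50)]
        cmap = CoordinateMap(
            [(GenomicPosition("1", 10), GenomicPosition("1", 11)),
             (GenomicPosition("1", 20), GenomicPosition("1", 22))]
        )
        ref = panel([site("2", 99, rsid="rs30", assembly="new")], name="ref",
                    assembly="new")
        converted, failed = liftover_sites(panel(sites), cmap)
        rescued, lost = rescue_failed_by_rsid(failed, ref)
        assert len(converted) + len(rescued) + len(lost) == len(sites)
        assert (len(converted), len(rescued), len(lost)) == (2, 1, 2)


class TestDedup:
    def _datasets(self):
        p1 = panel([site("1", 100, rsid="rs1", assembly="new")], name="p1",
                   assembly="new")
        p2 = panel([site("1", 100, rsid="rs2", assembly="new")], name="p2",
                   assembly="new")
        return {"p1": p1, "p2": p2}

    def test_deterministic_single_survivor(self):
        out1 = dedup_rsids(self._datasets(), seed=5)
        out2 = dedup_rsids(self._datasets(), seed=5)
        pos = GenomicPosition("1", 100)
        chosen1 = out1["p1"].sites[pos].rsid
        assert chosen1 in {"rs1", "rs2"}
        assert chosen1 == out1["p2"].sites[pos].rsid  # consistent across datasets
        assert chosen1 == out2["p1"].sites[pos].rsid  # reproducible under the seed

    def test_single_rsid_unchanged(self):
        p = panel([site("1", 100, rsid="rs1", assembly="new")], name="p",
                   assembly="new")
        out = dedup_rsids({"p": p}, seed=0)
        assert out["p"].sites[GenomicPosition("1", 100)].rsid == "rs1"

    def test_survivors_from_original_sets_and_bijection(self):
        rng = np.random.default_rng(2)
        sites1, sites2 = [], []
        originals = {}
        for i in range(5):
            pos = 100 + i * 10
            r1, r2 = f"rsA{i}", f"rsB{i}"
            originals[GenomicPosition("1", pos)] = {r1, r2}
            sites1.append(site("1", pos, rsid=r1, assembly="new"))
            sites2.append(site("1", pos, rsid=r2, assembly="new"))
        out = dedup_rsids(
            {"p1": panel(sites1, "p1", "new"), "p2": panel(sites2, "p2", "new")},
            seed=int(rng.integers(100)),
        )
        seen_rsids = {}
        for name in ("p1", "p2"):
            for pos, s in out[name].sites.items():
                assert s.rsid in originals[pos]
                seen_rsids.setdefault(s.rsid, set()).add(pos)
        # post-dedup the rsid→position relation is one-to-one
        assert all(len(v) == 1 for v in seen_rsids.values())


def test_merge_panels_union_first_wins():
    p1 = panel([site("1", 100, rsid="rs1", assembly="new")], "a", "new")
    p2 = panel([site("1", 100, rsid="rsX", assembly="new"),
                site("1", 200, rsid="rs2", assembly="new")], "b", "new")
    merged = merge_panels("m", p1, p2)
    assert len(merged) == 2
    assert merged.sites[GenomicPosition("1", 100)].rsid == "rs1"
    with pytest.raises(ValueError):
        merge_panels("m", p1, panel([site("1", 5)], "old", "old"))
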