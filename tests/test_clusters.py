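"""Cluster calling: gap arithmetic, proximity closure, completeness,
contig-majority filtering, paralog labelling, accessory chaining."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtrscan.clusters import (
    attach_accessory_mtrC,
    call_candidate_clusters,
    call_clusters,
    catalog_neighborhood,
    filter_complete,
    filter_contig_majority,
    gene_gap,
    label_cluster_order,
)
from mtrscan.curation import filter_domain_hits
from mtrscan.model import (
    CurationParams,
    GeneFeature,
    GenomeAnnotation,
    MtrCluster,
    ProteinHit,
    TaxonRecord,
)

PARAMS = CurationParams()


def _feat(fid, start, end, replicon="c1", product="other:hyp", pid=None, genome="G"):
    return GeneFeature(fid, genome, replicon, start, end, "+", product, pid or fid)


def _hit(pid, fam, evalue=1e-40):
    return ProteinHit(fam, pid, evalue, 100.0, 80.0)


def _taxon(genome="G", family="FamilyX", genus="Genus", assembly="isolate"):
    return TaxonRecord(genome, "P", "C", "O", family, genus, "spx", "s1", assembly)


class TestGeneGap:
    def test_adjacent_features_gap_zero(self):
        assert gene_gap(_feat("a", 1, 1000), _feat("b", 1001, 2000)) == 0

    def test_boundary_arithmetic(self):
        assert gene_gap(_feat("a", 1, 1000), _feat("b", 4501, 5000)) == 3500

    def test_overlap_clamps_to_zero(self):
        assert gene_gap(_feat("a", 1, 1000), _feat("b", 500, 1500)) == 0

    def test_symmetric(self):
        a, b = _feat("a", 1, 100), _feat("b", 700, 900)
        assert gene_gap(a, b) == gene_gap(b, a) == 599

    def test_different_replicons_error(self):
        with pytest.raises(ValueError, match="different replicons"):
            gene_gap(_feat("a", 1, 10, "c1"), _feat("b", 1, 10, "c2"))

    def test_start_start_mode(self):
        assert gene_gap(_feat("a", 100, 1000), _feat("b", 4000, 5000), "start_start") == 3900


def _chain(gaps, start=1, length=1000, fams=None):
    """Features laid end to end with the given inter-feature gaps."""
    feats, pos = [], start
    for i in range(len(gaps) + 1):
        feats.append(_feat(f"f{i}", pos, pos + length - 1))
        pos += length + (gaps[i] if i < len(gaps) else 0)
    hits = [
        _hit(f.protein_id, (fams or ["mtrC", "mtrA", "mtrB"] * 10)[i])
        for i, f in enumerate(feats)
    ]
    return feats, hits


class TestCandidateClusters:
    def test_gap_3400_joins_three_genes(self):
        feats, hits = _chain([3400, 3400])
        (c,) = call_candidate_clusters(feats, hits, PARAMS)
        assert len(c.core) == 3

    def test_gap_3500_joins_3501_splits(self):
        feats, hits = _chain([3500])
        assert len(call_candidate_clusters(feats, hits, PARAMS)) == 1
        feats, hits = _chain([3501])
        assert len(call_candidate_clusters(feats, hits, PARAMS)) == 2

    def test_transitive_chaining_beyond_pairwise_reach(self):
        feats, hits = _chain([3000, 3000])
        # first and last are >3,500 bp apart but connected through the middle
        assert gene_gap(feats[0], feats[2]) > 3500
        (c,) = call_candidate_clusters(feats, hits, PARAMS)
        assert len(c.core) == 3

    def test_order_string_reflects_genomic_order(self):
        feats, hits = _chain([200, 200], fams=["mtrC", "mtrA", "mtrB"])
        (c,) = call_candidate_clusters(feats, hits, PARAMS)
        assert c.order_string == "C-A-B"

    def test_permutation_invariance(self):
        feats, hits = _chain([500, 4000, 200, 200])
        expected = [
            (c.cluster_id, c.order_string)
            for c in call_candidate_clusters(feats, hits, PARAMS)
        ]
        rng = random.Random(5)
        for _ in range(5):
            fs, hs = list(feats), list(hits)
            rng.shuffle(fs)
            rng.shuffle(hs)
            got = [(c.cluster_id, c.order_string) for c in call_candidate_clusters(fs, hs, PARAMS)]
            assert got == expected

    @given(
        gaps=st.lists(st.integers(min_value=0, max_value=8000), min_size=1, max_size=12),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_transitive_closure(self, gaps):
        feats, hits = _chain(gaps)
        called = call_candidate_clusters(feats, hits, PARAMS)
        # brute force: connected components of the pairwise proximity graph
        n = len(feats)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if gene_gap(feats[i], feats[j]) <= PARAMS.proximity_bp:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), set()).add(feats[i].feature_id)
        expected = {frozenset(s) for s in comps.values()}
        got = {frozenset(f.feature_id for f, _ in c.core) for c in called}
        assert got == expected

    @given(
        gaps=st.lists(st.integers(min_value=0, max_value=8000), min_size=1, max_size=10),
        bump=st.integers(min_value=0, max_value=5000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_proximity_threshold(self, gaps, bump):
        feats, hits = _chain(gaps)
        small = call_candidate_clusters(feats, hits, PARAMS)
        big = call_candidate_clusters(
            feats, hits, CurationParams(proximity_bp=PARAMS.proximity_bp + bump)
        )
        # every cluster under the small threshold is contained in one big cluster
        big_sets = [{f.feature_id for f, _ in c.core} for c in big]
        for c in small:
            ids = {f.feature_id for f, _ in c.core}
            assert any(ids <= b for b in big_sets)


class TestCompleteness:
    def _cluster(self, fams, gaps=None):
        feats, _ = _chain(gaps or [200] * (len(fams) - 1))
        core = [(f, fam) for f, fam in zip(feats, fams)]
        return MtrCluster("c", "G", "c1", core=core, order_string="-".join(fams))

    def test_two_of_three_removed(self):
        kept, removed = filter_complete([self._cluster(["A", "B"])])
        assert kept == [] and len(removed) == 1
        assert "incomplete" in removed[0].flags

    def test_any_order_complete_kept(self):
        for fams in (["C", "A", "B"], ["A", "B", "C"], ["B", "C", "A"]):
            kept, removed = filter_complete([self._cluster(fams)])
            assert len(kept) == 1 and removed == []

    def test_tandem_duplicate_split_into_two_complete_cores(self):
        kept, removed = filter_complete([self._cluster(["C", "A", "B", "C", "A", "B"])])
        assert len(kept) == 2 and removed == []
        assert all(c.is_complete() for c in kept)
        assert [c.order_string for c in kept] == ["C-A-B", "C-A-B"]

    def test_extra_mtrC_demoted_to_accessory(self):
        kept, removed = filter_complete([self._cluster(["C", "A", "B", "C"])])
        assert len(kept) == 1 and removed == []
        assert len(kept[0].accessory_mtrC) == 1


class TestContigMajority:
    def _mag_with_contig(self, n_total, n_cluster=3):
        feats = [
            _feat(f"f{i}", 1 + i * 2000, 1000 + i * 2000, "ctg1", genome="M")
            for i in range(n_total)
        ]
        ann = GenomeAnnotation("M", _taxon("M", assembly="MAG"), {"ctg1": feats})
        core = [(feats[i], "CAB"[i]) for i in range(n_cluster)]
        cluster = MtrCluster("c", "M", "ctg1", core=core, order_string="C-A-B")
        return cluster, {"M": ann}

    def test_mag_contig_11_genes_3_in_cluster_removed(self):
        cluster, anns = self._mag_with_contig(11)
        kept, removed = filter_contig_majority([cluster], anns, PARAMS)
        assert kept == [] and len(removed) == 1
        assert "contig_majority_removed" in removed[0].flags

    def test_mag_contig_12_genes_kept(self):
        cluster, anns = self._mag_with_contig(12)
        kept, removed = filter_contig_majority([cluster], anns, PARAMS)
        assert len(kept) == 1 and removed == []

    def test_isolate_never_filtered(self):
        cluster, anns = self._mag_with_contig(5)
        anns["M"].taxon = _taxon("M", assembly="isolate")
        kept, removed = filter_contig_majority([cluster], anns, PARAMS)
        assert len(kept) == 1 and removed == []


class TestOrderLabelling:
    def _complete(self, order):
        feats, _ = _chain([200, 200])
        core = list(zip(feats, order))
        return MtrCluster("c", "G", "c1", core=core, order_string="-".join(order))

    def test_shewanellaceae_abc_is_def(self):
        c = label_cluster_order(self._complete("ABC"), _taxon(family="Shewanellaceae"))
        assert c.label == "DEF"

    def test_shewanellaceae_cab_is_cab(self):
        c = label_cluster_order(self._complete("CAB"), _taxon(family="Shewanellaceae"))
        assert c.label == "CAB"

    def test_other_taxa_abc_stays_cab_with_order_retained(self):
        c = label_cluster_order(self._complete("ABC"), _taxon(family="Ectothiorhodospiraceae"))
        assert c.label == "CAB" and c.order_string == "A-B-C"

    def test_incomplete_cluster_is_labelling_error(self):
        feats, _ = _chain([200])
        c = MtrCluster("c", "G", "c1", core=[(feats[0], "A"), (feats[1], "B")])
        with pytest.raises(ValueError, match="incomplete"):
            label_cluster_order(c, _taxon())


class TestAccessoryChaining:
    def _core_cluster(self):
        feats, _ = _chain([200, 200], fams=["mtrC", "mtrA", "mtrB"])
        return (
            MtrCluster(
                "c", "G", "c1",
                core=[(feats[0], "C"), (feats[1], "A"), (feats[2], "B")],
                order_string="C-A-B",
            ),
            feats,
        )

    def test_adjacent_omcA_attached(self):
        cluster, feats = self._core_cluster()
        omcA = _feat("omcA", feats[-1].end + 201, feats[-1].end + 1200, pid="omcA")
        cluster2 = attach_accessory_mtrC(
            cluster, [_hit("omcA", "mtrC", 1e-30)], feats + [omcA], PARAMS
        )
        assert [f.feature_id for f in cluster2.accessory_mtrC] == ["omcA"]

    def test_distant_homolog_without_intermediate_not_attached(self):
        cluster, feats = self._core_cluster()
        far = _feat("far", feats[-1].end + 5001, feats[-1].end + 6000, pid="far")
        cluster2 = attach_accessory_mtrC(cluster, [_hit("far", "mtrC", 1e-30)], feats + [far], PARAMS)
        assert cluster2.accessory_mtrC == []

    def test_chaining_to_fixpoint(self):
        cluster, feats = self._core_cluster()
        omcA = _feat("omcA", feats[-1].end + 3001, feats[-1].end + 4000, pid="omcA")
        undA = _feat("undA", omcA.end + 3001, omcA.end + 4000, pid="undA")
        cluster2 = attach_accessory_mtrC(
            cluster,
            [_hit("omcA", "mtrC", 1e-30), _hit("undA", "mtrC", 1e-30)],
            feats + [omcA, undA],
            PARAMS,
        )
        assert {f.feature_id for f in cluster2.accessory_mtrC} == {"omcA", "undA"}

    def test_weak_evalue_excluded(self):
        cluster, feats = self._core_cluster()
        weak = _feat("weak", feats[-1].end + 201, feats[-1].end + 1200, pid="weak")
        cluster2 = attach_accessory_mtrC(cluster, [_hit("weak", "mtrC", 1e-9)], feats + [weak], PARAMS)
        assert cluster2.accessory_mtrC == []

    def test_duplicate_protein_ids_collapsed(self):
        cluster, feats = self._core_cluster()
        a = _feat("dupA", feats[-1].end + 201, feats[-1].end + 1200, pid="shared")
        b = _feat("dupB", a.end + 201, a.end + 1200, pid="shared")
        cluster2 = attach_accessory_mtrC(cluster, [_hit("shared", "mtrC", 1e-30)], feats + [a, b], PARAMS)
        assert [f.feature_id for f in cluster2.accessory_mtrC] == ["dupA"]


class TestNeighborhood:
    def _annotated_cluster(self, n_left, n_right):
        feats = []
        pos = 1
        for i in range(n_left):
            feats.append(_feat(f"L{i}", pos, pos + 999, product="ccm"))
            pos += 1500
        core_feats = []
        for i, fam in enumerate("CAB"):
            f = _feat(f"core{fam}", pos, pos + 999, product=f"mtr{fam}_like")
            core_feats.append((f, fam))
            feats.append(f)
            pos += 1500
        for i in range(n_right):
            feats.append(_feat(f"R{i}", pos, pos + 999, product="frd"))
            pos += 1500
        ann = GenomeAnnotation("G", _taxon(), {"c1": feats})
        return MtrCluster("c", "G", "c1", core=core_feats, order_string="C-A-B"), ann

    def test_contig_edge_gives_one_sided_catalog(self):
        cluster, ann = self._annotated_cluster(0, 4)
        catalog_neighborhood(cluster, ann, 10)
        assert all(off > 0 for _, off in cluster.neighborhood)
        assert len(cluster.neighborhood) == 4

    def test_planted_flank_tokens_present_with_signed_offsets(self):
        cluster, ann = self._annotated_cluster(3, 2)
        catalog_neighborhood(cluster, ann, 10)
        labels = {off: f.product_label for f, off in cluster.neighborhood}
        assert labels[-1] == "ccm" and labels[1] == "frd"
        assert sorted(labels) == [-3, -2, -1, 1, 2]

    def test_zero_window_empty_catalog(self):
        cluster, ann = self._annotated_cluster(3, 3)
        catalog_neighborhood(cluster, ann, 0)
        assert cluster.neighborhood == []


class TestEndToEndPlantedRecovery:
    def test_called_clusters_match_truth_exactly(self, forged_dataset):
        _, (anns, hits, doms, truth) = forged_dataset
        kept_hits, _ = filter_domain_hits(hits, doms)
        clusters, _ = call_clusters({a.genome_id: a for a in anns}, kept_hits, PARAMS)
        truth_cores = {frozenset(p.core_feature_ids) for p in truth.planted}
        called_cores = {frozenset(f.feature_id for f, _ in c.core) for c in clusters}
        assert called_cores == truth_cores  # sensitivity 1, FDR 0
        # accessory recovery too
        truth_acc = {frozenset(p.accessory_feature_ids) for p in truth.planted if p.accessory_feature_ids}
        called_acc = {
            frozenset(f.feature_id for f in c.accessory_mtrC) for c in clusters if c.accessory_mtrC
        }
        assert called_acc == truth_acc
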