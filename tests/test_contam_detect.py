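import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from sagqc import contam_detect as cd
from sagqc.sequence_io import Assembly, Contig, Sequence

from conftest import make_mixture


def dbscan_oracle(points, eps, min_pts):
    """Brute-force density connectivity: transitive closure over core points.

    Returns (core mask, list of clusters as frozensets of core indices,
    border membership map index -> set of admissible clusters).
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    dist = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    within = dist <= eps
    core = within.sum(axis=1) >= min_pts
    # connected components of the eps-graph restricted to core points
    core_idx = np.flatnonzero(core)
    parent = {i: i for i in core_idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in core_idx:
        for j in core_idx:
            if within[i, j]:
                parent[find(i)] = find(j)
    clusters: dict[int, set] = {}
    for i in core_idx:
        clusters.setdefault(find(i), set()).add(i)
    comp_list = list(clusters.values())
    border_options = {}
    for i in range(n):
        if core[i]:
            continue
        opts = {k for k, comp in enumerate(comp_list)
                if any(within[i, j] for j in comp)}
        border_options[i] = opts
    return core, comp_list, border_options


def assert_matches_oracle(points, eps, min_pts):
    labeling = cd.dbscan(points, eps, min_pts)
    core, comps, border_options = dbscan_oracle(points, eps, min_pts)
    np.testing.assert_array_equal(labeling.core, core)
    # core points partition exactly into the oracle components
    got = {}
    for comp in comps:
        labs = {labeling.labels[i] for i in comp}
        assert len(labs) == 1
        lab = labs.pop()
        assert lab != cd.NOISE and lab not in got.values()
        got[frozenset(comp)] = lab
    comp_of_label = {lab: comp for comp, lab in got.items()}
    for i, opts in border_options.items():
        lab = labeling.labels[i]
        if not opts:
            assert lab == cd.NOISE
        else:
            assert lab != cd.NOISE
            comp = comp_of_label[lab]
            assert any(frozenset(comps[k]) == comp for k in opts)


class TestDbscan:
    def test_two_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(5, 2))
        b = rng.normal(10, 0.1, size=(5, 2))
        pts = np.vstack([a, b])
        labeling = cd.dbscan(pts, eps=1.0, min_pts=3)
        assert labeling.n_clusters == 2
        assert not np.any(labeling.labels == cd.NOISE)

    def test_single_point_is_noise(self):
        labeling = cd.dbscan(np.zeros((1, 2)), eps=0.5, min_pts=4)
        assert labeling.labels.tolist() == [cd.NOISE]

    def test_identical_points_one_cluster(self):
        labeling = cd.dbscan(np.zeros((6, 3)), eps=0.5, min_pts=4)
        assert labeling.n_clusters == 1
        assert np.all(labeling.labels == 0)

    def test_empty_input(self):
        labeling = cd.dbscan(np.empty((0, 2)), eps=0.5, min_pts=3)
        assert labeling.labels.size == 0

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            dim = int(rng.integers(1, 4))
            pts = rng.normal(0, 1, size=(n, dim))
            if rng.random() < 0.5:  # sometimes add a tight clump
                pts[: n // 2] *= 0.05
            eps = float(rng.uniform(0.05, 1.5))
            min_pts = int(rng.integers(1, 6))
            assert_matches_oracle(pts, eps, min_pts)

    def test_matches_sklearn_cross_check(self):
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(7)
        for seed in range(20):
            pts = rng.normal(0, 1, size=(40, 3))
            eps, min_pts = 0.8, 4
            ours = cd.dbscan(pts, eps, min_pts)
            ref = SkDBSCAN(eps=eps, min_samples=min_pts).fit(pts)
            ref_core = np.zeros(len(pts), bool)
            ref_core[ref.core_sample_indices_] = True
            np.testing.assert_array_equal(ours.core, ref_core)
            # identical noise sets; identical partition of the core points
            np.testing.assert_array_equal(ours.labels == cd.NOISE,
                                          ref.labels_ == -1)
            for lab in set(ref.labels_[ref_core]):
                ours_labs = set(ours.labels[ref_core][ref.labels_[ref_core] == lab])
                assert len(ours_labs) == 1

    def test_permutation_invariance_of_core_and_noise(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, size=(30, 2))
        perm = rng.permutation(30)
        a = cd.dbscan(pts, 0.6, 3)
        b = cd.dbscan(pts[perm], 0.6, 3)
        np.testing.assert_array_equal(a.core[perm], b.core)
        np.testing.assert_array_equal((a.labels == cd.NOISE)[perm],
                                      b.labels == cd.NOISE)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cd.dbscan(np.zeros((3, 2)), eps=0.0, min_pts=3)
        with pytest.raises(ValueError):
            cd.dbscan(np.zeros((3, 2)), eps=1.0, min_pts=0)


class TestChooseEps:
    def test_separates_two_tight_clusters(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.05, size=(20, 2)),
                         rng.normal(5, 0.05, size=(20, 2))])
        eps = cd.choose_eps(pts, min_pts=4)
        labeling = cd.dbscan(pts, eps, 4)
        assert labeling.n_clusters == 2

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, size=(30, 3))
        e1 = cd.choose_eps(pts, 4)
        e2 = cd.choose_eps(pts * 17.0, 4)
        assert e2 == pytest.approx(17.0 * e1, rel=1e-9)

    def test_positive_on_uniform_points(self):
        rng = np.random.default_rng(3)
        assert cd.choose_eps(rng.random((50, 2)), 4) > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cd.choose_eps(np.zeros((3, 2)), min_pts=4)


class TestLabelContigs:
    def _labeling(self, labels):
        arr = np.asarray(labels)
        return cd.ClusterLabeling(labels=arr, core=arr >= 0, eps=1.0, min_pts=3)

    def test_single_cluster_all_valid(self):
        ids = ["a", "b", "c"]
        rep = cd.label_contigs(self._labeling([0, 0, 0]),
                               {i: 1000 for i in ids}, ids)
        assert all(v == "valid" for v in rep.status.values())

    def test_main_cluster_by_base_pair_mass(self):
        # cluster 0: 10 contigs x 10 kb; cluster 1: 20 contigs x 1 kb
        ids = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(20)]
        lengths = {i: 10_000 for i in ids[:10]} | {i: 1000 for i in ids[10:]}
        rep = cd.label_contigs(self._labeling([0] * 10 + [1] * 20), lengths, ids)
        assert rep.main_cluster_id == 0
        assert all(rep.status[i] == "valid" for i in ids[:10])
        assert all(rep.status[i] == "contaminant" for i in ids[10:])

    def test_noise_flagged_contaminant(self):
        ids = ["a", "b", "c", "d"]
        rep = cd.label_contigs(self._labeling([0, 0, 0, -1]),
                               {i: 1000 for i in ids}, ids)
        assert rep.status["d"] == "contaminant"
        assert rep.rationale["d"] == "density_noise"

    def test_all_noise_raises(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError, match="noise"):
            cd.label_contigs(self._labeling([-1, -1]),
                             {i: 1000 for i in ids}, ids)


class TestRefineWithTaxonomy:
    def _report(self):
        return cd.ContamReport(
            status={"a": "valid", "b": "contaminant", "c": "contaminant"},
            rationale={"a": "main_cluster_0", "b": "density_noise",
                       "c": "minor_cluster_1"},
            main_cluster_id=0)

    def test_matching_taxon_reclassified(self):
        calls = cd.TaxonomyCall(genes={"g1": ("b", "HostTaxon", 1.0)})
        rep = cd.refine_with_taxonomy(self._report(), calls, {"HostTaxon"})
        assert rep.status["b"] == "reclassified_valid"

    def test_disjoint_taxon_stays_contaminant(self):
        calls = cd.TaxonomyCall(genes={"g1": ("b", "OtherTaxon", 1.0)})
        rep = cd.refine_with_taxonomy(self._report(), calls, {"HostTaxon"})
        assert rep.status["b"] == "contaminant"

    def test_missing_calls_annotated(self):
        rep = cd.refine_with_taxonomy(self._report(), cd.TaxonomyCall(),
                                      {"HostTaxon"})
        assert rep.status["c"] == "contaminant"
        assert "no_taxonomy" in rep.rationale["c"]

    def test_never_demotes_valid(self):
        calls = cd.TaxonomyCall(genes={"g1": ("a", "OtherTaxon", 1.0)})
        rep = cd.refine_with_taxonomy(self._report(), calls, {"HostTaxon"})
        assert rep.status["a"] == "valid"

    def test_monotone_valid_set(self):
        before = self._report()
        calls = cd.TaxonomyCall(genes={"g1": ("b", "HostTaxon", 1.0)})
        after = cd.refine_with_taxonomy(before, calls, {"HostTaxon"})
        valid_before = set(before.contigs_with_status("valid",
                                                      "reclassified_valid"))
        valid_after = set(after.contigs_with_status("valid",
                                                    "reclassified_valid"))
        assert valid_before <= valid_after


class TestDecontaminate:
    def test_two_genome_mixture_separated(self):
        mixed, truth = make_mixture(seed=100)
        valid, report, diag = cd.decontaminate(mixed)
        contam_true = {c for c, l in truth.labels.items() if l == "contaminant"}
        host_true = set(truth.labels) - contam_true
        flagged = set(report.contigs_with_status("contaminant"))
        kept = set(valid.contig_ids())
        assert len(contam_true & flagged) / len(contam_true) >= 0.9
        assert len(host_true & kept) / len(host_true) >= 0.9

    def test_status_counts_conserved(self):
        mixed, _ = make_mixture(seed=101)
        _, report, _ = cd.decontaminate(mixed)
        assert set(report.status) == set(mixed.contig_ids())

    def test_pure_assembly_with_mock_taxonomy_keeps_everything(self):
        from sagqc import synthetic_data as sd
        g = sd.make_genome(sd.GenomeModel(name="pure", length=250_000,
                                          gc_content=0.45, seed=5))
        asm, _ = sd.fragment_genome(g, f=1.0, contig_len_mean=5000, seed=6,
                                    sigma=0.1)
        calls = cd.TaxonomyCall(genes={
            f"g{i}": (c.id, "host_taxon", 1.0)
            for i, c in enumerate(asm.contigs)})
        config = cd.DecontamConfig(taxonomy=calls)
        valid, report, _ = cd.decontaminate(asm, config)
        n_flagged = len(report.contigs_with_status("contaminant"))
        assert n_flagged == 0
        assert len(valid.contigs) == len(asm.contigs)

    def test_tiny_eps_error_path(self):
        from sagqc import synthetic_data as sd
        g = sd.make_genome(sd.GenomeModel(name="g", length=100_000,
                                          gc_content=0.5, seed=8))
        asm, _ = sd.fragment_genome(g, f=1.0, contig_len_mean=5000, seed=9)
        config = cd.DecontamConfig(eps=1e-12)
        with pytest.raises(ValueError, match="noise"):
            cd.decontaminate(asm, config)

    def test_single_contig_assembly_rejected(self):
        asm = Assembly(name="one", contigs=[
            Contig(Sequence(id="c1", residues="ACGT" * 1000))])
        with pytest.raises(ValueError):
            cd.decontaminate(asm)
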