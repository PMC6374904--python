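"""Reference library build/query and the leave-out evaluation protocol."""

import itertools

import numpy as np
import pytest

import skimdist as sd

from conftest import K

S = 10**5  # sketch size for desk-scale fixtures


@pytest.fixture(scope="module")
def skim_files(tmp_path_factory):
    """Four 60-kb taxa skimmed at 2x, written as FASTQ."""
    root = tmp_path_factory.mktemp("skims")
    rng = np.random.default_rng(31)
    base = sd.random_genome(60_000, rng)
    paths = []
    for i, d in enumerate((0.0, 0.05, 0.12, 0.20)):
        genome = sd.mutate_genome(base, d, rng) if d else base
        reads = sd.sample_reads(genome, 2.0, 100, 0.005, rng)
        path = root / f"taxon{i}.fq"
        sd.write_fastq(reads, path)
        paths.append(path)
    return paths


@pytest.fixture(scope="module")
def library(skim_files, tmp_path_factory):
    out = tmp_path_factory.mktemp("lib")
    return sd.build_library(skim_files, out, k=K, s=S)


class TestBuildLibrary:
    def test_manifest_and_entries(self, library):
        assert library.names == [f"taxon{i}" for i in range(4)]
        assert library.k == K and library.s == S
        reopened = sd.ReferenceLibrary.open(library.root)
        assert reopened.names == library.names
        sk, prof = reopened.load_entry("taxon0")
        assert sk.k == K and prof.k == K and prof.coverage > 0

    def test_rebuild_is_byte_identical(self, skim_files, tmp_path):
        lib1 = sd.build_library(skim_files[:2], tmp_path / "l1", k=K, s=S)
        lib2 = sd.build_library(skim_files[:2], tmp_path / "l2", k=K, s=S)
        for name in lib1.names:
            s1, p1 = lib1.load_entry(name)
            s2, p2 = lib2.load_entry(name)
            assert np.array_equal(s1.hashes, s2.hashes) and p1 == p2

    def test_duplicate_names_rejected(self, skim_files, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            sd.build_library([skim_files[0], skim_files[0]], tmp_path / "dup")

    def test_unreadable_sample_skipped_with_warning(self, skim_files, tmp_path):
        bad = tmp_path / "broken.fq"
        bad.write_text("@only_header_no_sequence")
        with pytest.warns(UserWarning, match="skipping sample 'broken'"):
            lib = sd.build_library(list(skim_files[:3]) + [bad], tmp_path / "l3",
                                   k=K, s=S)
        assert lib.names == ["taxon0", "taxon1", "taxon2"]


class TestQuery:
    def test_library_member_is_its_own_best_match(self, library, skim_files):
        ranked = sd.query(library, skim_files[1])
        assert ranked[0] == ("taxon1", 0.0)
        assert [n for n, _ in ranked] == ["taxon1", "taxon0", "taxon2", "taxon3"]

    def test_mutated_copy_ranks_its_source_first(self, library, skim_files, tmp_path):
        rng = np.random.default_rng(33)
        # a fresh mutant of taxon0's genome at d=0.04 (seed 31 regenerates it)
        base = sd.random_genome(60_000, np.random.default_rng(31))
        mutant = sd.mutate_genome(base, 0.04, rng)
        qpath = tmp_path / "query.fq"
        sd.write_fastq(sd.sample_reads(mutant, 2.0, 100, 0.005, rng), qpath)
        ranked = sd.query(library, qpath)
        assert ranked[0][0] == "taxon0"
        assert ranked[0][1] == pytest.approx(0.04, rel=0.25)

    def test_empty_library_errors(self, tmp_path):
        lib = sd.ReferenceLibrary(root=tmp_path, names=[], k=K, s=S, hash_seed=42)
        with pytest.raises(ValueError, match="empty"):
            sd.query(lib, tmp_path / "x.fq")

    def test_rank_matches_ties_broken_by_name(self):
        p = sd.SkimProfile(k=K, mean_read_length=100, total_bases=10**6,
                           lam=1, coverage=1, genome_length=1e6, eta=1, zeta=1)
        h = np.array([1, 2, 3], dtype=np.uint64)
        sk = sd.Sketch(k=K, s=10, hash_seed=42, hashes=h)
        refs = {"b": (sk, p), "a": (sk, p)}
        ranked = sd.rank_matches((sk, p), refs)
        assert [n for n, _ in ranked] == ["a", "b"]


# ---------------------------------------------------------------------------
# leave-out protocol
# ---------------------------------------------------------------------------

def brute_force_leave_out(truth, method_order, d):
    """Independent re-statement of the protocol with explicit loops."""
    ranks, dists = [], []
    for q in truth:
        ordered = sorted(truth[q], key=lambda n: (truth[q][n], n))
        kept = [n for n in ordered if truth[q][n] > d]
        if len(kept) < 2:
            continue
        for name, _ in method_order[q]:
            if name in kept:
                pick = name
                break
        r = kept.index(pick) + 1
        ranks.append(r - 1)
        dists.append((truth[q][pick] - truth[q][kept[0]]) / truth[q][kept[0]])
    return sum(ranks) / len(ranks), sum(dists) / len(dists)


@pytest.fixture()
def six_taxon_example():
    names = list("ABCDEF")
    truth_mat = {
        ("A", "B"): 0.02, ("A", "C"): 0.04, ("A", "D"): 0.06,
        ("A", "E"): 0.08, ("A", "F"): 0.12, ("B", "C"): 0.03,
        ("B", "D"): 0.05, ("B", "E"): 0.09, ("B", "F"): 0.11,
        ("C", "D"): 0.045, ("C", "E"): 0.07, ("C", "F"): 0.10,
        ("D", "E"): 0.065, ("D", "F"): 0.09, ("E", "F"): 0.05,
    }
    # method estimates: truth plus deterministic perturbations that swap
    # some neighbours (e.g. D and E seen from A)
    bump = {("A", "D"): 0.07, ("A", "E"): 0.062, ("B", "E"): 0.085,
            ("B", "F"): 0.115, ("C", "E"): 0.105, ("C", "F"): 0.071}
    est_mat = {**truth_mat, **bump}

    def expand(mat):
        out = {q: {q: 0.0} for q in names}
        for (a, b), v in mat.items():
            out[a][b] = v
            out[b][a] = v
        return out

    truth = expand(truth_mat)
    est = expand(est_mat)
    method_order = {
        q: sorted(((n, v) for n, v in est[q].items()), key=lambda t: (t[1], t[0]))
        for q in names
    }
    return truth, method_order


class TestLeaveOut:
    def test_perfect_method_has_zero_errors(self, six_taxon_example):
        truth, _ = six_taxon_example
        perfect = {
            q: sorted(((n, v) for n, v in truth[q].items()), key=lambda t: (t[1], t[0]))
            for q in truth
        }
        res = sd.leave_out_eval(truth, perfect, [0.01, 0.03, 0.05])
        for rank_err, dist_err in res.values():
            assert rank_err == 0.0 and dist_err == 0.0

    def test_hand_computed_single_query(self):
        # 3 references; method's top pick is truth's 2nd best -> r-1 = 1
        truth = {"q": {"q": 0.0, "x": 0.06, "y": 0.08, "z": 0.12}}
        order = {"q": [("y", 0.062), ("x", 0.07), ("z", 0.125)]}
        res = sd.leave_out_eval(truth, order, [0.05])
        rank_err, dist_err = res[0.05]
        assert rank_err == 1.0
        assert dist_err == pytest.approx((0.08 - 0.06) / 0.06)

    def test_matches_brute_force_on_six_taxa(self, six_taxon_example):
        truth, method_order = six_taxon_example
        grid = [0.01, 0.02, 0.04, 0.06, 0.08]
        res = sd.leave_out_eval(truth, method_order, grid)
        for d in grid:
            expect = brute_force_leave_out(truth, method_order, d)
            assert res[d] == pytest.approx(expect)
        # the perturbations do produce nonzero error somewhere
        assert any(r > 0 for r, _ in res.values())

    def test_invariant_to_reference_order(self, six_taxon_example):
        truth, method_order = six_taxon_example
        shuffled_truth = {
            q: dict(sorted(truth[q].items(), key=lambda t: t[0], reverse=True))
            for q in sorted(truth, reverse=True)
        }
        a = sd.leave_out_eval(truth, method_order, [0.03])
        b = sd.leave_out_eval(shuffled_truth, method_order, [0.03])
        assert a == b

    def test_query_in_library_always_rank_zero(self, six_taxon_example):
        # threshold below every distance: the query itself (d=0) is removed,
        # every method that ranks its nearest neighbour first scores 0
        truth, _ = six_taxon_example
        perfect = {
            q: sorted(((n, v) for n, v in truth[q].items()), key=lambda t: (t[1], t[0]))
            for q in truth
        }
        res = sd.leave_out_eval(truth, perfect, [0.0])
        assert res[0.0] == (0.0, 0.0)

    def test_degenerate_queries_skipped(self):
        truth = {"q1": {"q1": 0.0, "x": 0.02, "y": 0.2, "z": 0.25},
                 "q2": {"q2": 0.0, "x": 0.5, "y": 0.6, "z": 0.9}}
        order = {q: [("x", 0.1), ("y", 0.2), ("z", 0.3)] for q in truth}
        with pytest.warns(UserWarning, match="skipped"):
            res = sd.leave_out_eval(truth, order, [0.21])
        assert res[0.21][0] == 0.0  # only q2 evaluable


class TestCladeSearch:
    def test_corrected_rank_error_not_worse_than_uncorrected(self):
        """8 mutants of one ancestor, 1x skims: corrected distances should
        search the library at least as well as uncorrected ones."""
        rng = np.random.default_rng(41)
        L = 400_000
        base = sd.random_genome(L, rng)
        radii = np.linspace(0.01, 0.06, 8)
        names = [f"t{i}" for i in range(8)]
        entries = []
        for name, r in zip(names, radii):
            genome = sd.mutate_genome(base, r, rng)
            reads = sd.sample_reads(genome, 1.0, 100, 0.01, rng)
            table = sd.count_kmers(reads, K)
            prof = sd.build_profile(sd.histogram(table), sd.read_stats(reads), K)
            entries.append((name, sd.build_sketch(table, s=10**6, m=prof.m), prof))

        truth = {
            a: {
                b: (0.0 if a == b else
                    sd.composed_distance(radii[i], radii[j]))
                for j, b in enumerate(names)
            }
            for i, a in enumerate(names)
        }
        corrected, raw = {}, {}
        for i, (qname, qsk, qprof) in enumerate(entries):
            cor, unc = [], []
            for j, (rname, rsk, rprof) in enumerate(entries):
                if i == j:
                    cor.append((rname, 0.0))
                    unc.append((rname, 0.0))
                    continue
                J = sd.jaccard(qsk, rsk)
                cor.append((rname, sd.skim_distance(J, qprof, rprof).D))
                unc.append((rname, sd.jaccard_to_distance(J, K).D))
            corrected[qname] = sorted(cor, key=lambda t: (t[1], t[0]))
            raw[qname] = sorted(unc, key=lambda t: (t[1], t[0]))

        grid = [0.02, 0.04, 0.06]
        res_cor = sd.leave_out_eval(truth, corrected, grid)
        res_raw = sd.leave_out_eval(truth, raw, grid)
        for d in grid:
            assert res_cor[d][0] <= res_raw[d][0], (
                f"d={d}: corrected rank error {res_cor[d][0]} vs raw {res_raw[d][0]}"
            )
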