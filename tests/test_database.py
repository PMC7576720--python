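"""Database construction: collision resolution, X% selection, serialization."""

import numpy as np
import pytest

from dktax import BuildParams, CodecParams, build_database, read_database, write_database
from dktax.codec import encode_bases, reverse_complement
from dktax.database import (
    collect_species_kmers,
    remove_cross_taxa,
    resolve_genus,
    select_kmers,
)
from dktax.errors import EmptyInputError, FormatError
from dktax.simulate import random_genome, simulate_taxonomy_and_genomes

P10 = BuildParams(codec=CodecParams(n=10, m=6), x_percent=15.0)
FWD = BuildParams(codec=CodecParams(n=10, m=6), x_percent=15.0, include_rc=False)


def naive_kmer_set(seq: str, params: BuildParams) -> set:
    """Pure-string reference: project every clean window to
    (first-n-bases, last-16-bases) and take the set union."""
    out = set()
    tracks = [seq]
    if params.include_rc:
        tracks.append(reverse_complement(seq))
    for s in tracks:
        s = s.upper()
        for i in range(len(s) - 31):
            w = s[i : i + 32]
            if set(w) <= set("ACGT"):
                out.add((w[: params.codec.n], w[16:]))
    return out


def as_string_keys(kmers, params) -> set:
    from dktax.codec import decode_bases

    return {
        (decode_bases(g, params.codec.n), decode_bases(s, 16)) for g, s in kmers
    }


class TestCollect:
    def test_duplicate_strains_collapse(self):
        g = random_genome(300, np.random.default_rng(0))
        one = collect_species_kmers([("a", g)], P10)
        two = collect_species_kmers([("a", g), ("b", g)], P10)
        assert set(one) == set(two)

    def test_window_count_bound(self):
        g = random_genome(35, np.random.default_rng(1))
        kmers = collect_species_kmers([("a", g)], FWD)
        assert len(kmers) <= 35 - 32 + 1

    def test_matches_naive_windowing_oracle(self):
        rng = np.random.default_rng(2)
        g = random_genome(800, rng)
        g = g[:300] + g[100:200] + g[300:]  # plant a duplicated segment
        kmers = collect_species_kmers([("a", g)], P10)
        assert as_string_keys(kmers, P10) == naive_kmer_set(g, P10)

    def test_ambiguous_windows_skipped(self):
        g = "ACGT" * 10 + "N" + "ACGT" * 10
        kmers = collect_species_kmers([("a", g)], FWD)
        naive = naive_kmer_set(g, FWD)
        assert as_string_keys(kmers, FWD) == naive

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            collect_species_kmers([("a", "ACGT")], P10)


@pytest.fixture(scope="module")
def two_genus_fixture():
    """Two genera x two species with planted within-genus sharing."""
    return simulate_taxonomy_and_genomes(
        n_genera=2, species_per_genus=2, genome_length=2000,
        shared_fraction=0.25, seed=11,
    )


class TestResolveGenus:
    def test_assignment_matches_multiplicity_oracle(self, two_genus_fixture):
        tree, genomes, seqtax = two_genus_fixture
        sets = {
            seqtax[sid]: collect_species_kmers([(sid, genomes[sid])], FWD)
            for sid in sorted(genomes)
        }
        assigned = resolve_genus(sets, tree)
        for key, taxids in assigned.items():
            present_in = [sp for sp, km in sets.items() if key in km]
            expected = set()
            by_genus = {}
            for sp in present_in:
                by_genus.setdefault(tree.ancestor_at_rank(sp, "genus"), []).append(sp)
            for genus, sps in by_genus.items():
                expected.add(genus if len(sps) >= 2 else sps[0])
            assert taxids == expected

    def test_unique_kmer_keeps_species_taxid(self, two_genus_fixture):
        tree, genomes, seqtax = two_genus_fixture
        sid = sorted(genomes)[0]
        sp = seqtax[sid]
        sets = {sp: collect_species_kmers([(sid, genomes[sid])], FWD)}
        assigned = resolve_genus(sets, tree)
        assert all(t == {sp} for t in assigned.values())

    def test_shared_kmers_promoted_to_genus(self, two_genus_fixture):
        tree, genomes, seqtax = two_genus_fixture
        sets = {
            seqtax[sid]: collect_species_kmers([(sid, genomes[sid])], FWD)
            for sid in sorted(genomes)[:2]  # the two species of genus 100
        }
        assigned = resolve_genus(sets, tree)
        genus_assigned = [k for k, t in assigned.items() if t == {100}]
        assert genus_assigned  # the planted shared segment produced some
        sp_a, sp_b = sorted(sets)
        for key in genus_assigned:
            assert key in sets[sp_a] and key in sets[sp_b]


class TestSelection:
    def test_x100_is_identity(self, two_genus_fixture):
        tree, genomes, seqtax = two_genus_fixture
        sid = sorted(genomes)[0]
        kmers = collect_species_kmers([(sid, genomes[sid])], FWD)
        assign = {k: seqtax[sid] for k in kmers}
        full = BuildParams(codec=FWD.codec, x_percent=100, include_rc=False)
        assert select_kmers(assign, kmers, tree, full) == assign

    def test_stride_keeps_expected_fraction(self):
        """X=15 over 10,000 window positions keeps 10,000/7 +- 1 k-mers."""
        rng = np.random.default_rng(5)
        tree, _, _ = simulate_taxonomy_and_genomes(1, 1, 100, seed=5)
        g = random_genome(10_000 + 31, rng)
        kmers = collect_species_kmers([("a", g)], FWD)
        assert len(kmers) == 10_000  # all windows distinct for a random 10 kb
        assign = {k: 1000 for k in kmers}
        kept = select_kmers(assign, kmers, tree, FWD)
        assert abs(len(kept) - 10_000 / 7) <= 1

    def test_genus_kmers_survive_any_x(self, two_genus_fixture):
        tree, genomes, seqtax = two_genus_fixture
        for x in (5, 15, 50):
            params = BuildParams(codec=FWD.codec, x_percent=x, include_rc=False)
            db = build_database(genomes, seqtax, tree, params)
            genus_kmers = int((db.taxids == 100).sum() + (db.taxids == 101).sum())
            full = build_database(
                genomes, seqtax, tree,
                BuildParams(codec=FWD.codec, x_percent=100, include_rc=False),
            )
            genus_full = int((full.taxids == 100).sum() + (full.taxids == 101).sum())
            assert genus_kmers == genus_full


class TestCrossTaxaRemoval:
    def test_multi_taxid_kmers_dropped(self):
        assigned = {(1, 2): {1000}, (3, 4): {1000, 1010}, (5, 6): {100}}
        out = remove_cross_taxa(assigned)
        assert out == {(1, 2): 1000, (5, 6): 100}

    def test_cross_genus_shared_segment_removed(self):
        rng = np.random.default_rng(21)
        tree, genomes, seqtax = simulate_taxonomy_and_genomes(2, 1, 1500, seed=21)
        sids = sorted(genomes)
        shared = random_genome(200, rng)
        genomes[sids[0]] = genomes[sids[0]][:500] + shared + genomes[sids[0]][700:]
        genomes[sids[1]] = genomes[sids[1]][:900] + shared + genomes[sids[1]][1100:]
        full = BuildParams(codec=FWD.codec, x_percent=100, include_rc=False)
        db = build_database(genomes, seqtax, tree, full)
        stored = as_string_keys(
            _db_kmer_keys(db), full
        )
        for i in range(len(shared) - 31):
            w = shared[i : i + 32]
            assert (w[:10], w[16:]) not in stored


def _db_kmer_keys(db):
    keys = []
    sizes = db.group_size
    pos = 0
    for gid in np.nonzero(sizes)[0]:
        lo = int(db.offsets[gid])
        for j in range(lo, lo + int(sizes[gid])):
            keys.append((int(gid), int(db.suffixes[j])))
    return keys


class TestBuild:
    def test_empty_genome_set(self, two_genus_fixture):
        tree, _, _ = two_genus_fixture
        db = build_database({}, {}, tree, P10)
        assert db.n_kmers == 0
        assert int(db.group_size.sum()) == 0

    def test_rebuild_is_byte_identical(self, two_genus_fixture, tmp_path):
        tree, genomes, seqtax = two_genus_fixture
        paths = []
        for run in ("a", "b"):
            db = build_database(genomes, seqtax, tree, P10)
            out = tmp_path / run
            write_database(db, str(out))
            paths.append(out)
        for fname in ("header.json", "size.bin", "suffix.bin", "taxid.bin"):
            assert (paths[0] / fname).read_bytes() == (paths[1] / fname).read_bytes()

    def test_x_monotonicity(self, two_genus_fixture):
        """The k-mer set at X=10 is a subset of the set at X=20."""
        tree, genomes, seqtax = two_genus_fixture
        dbs = {}
        for x in (10, 20):
            params = BuildParams(codec=FWD.codec, x_percent=x, include_rc=False)
            dbs[x] = set(_db_kmer_keys(build_database(genomes, seqtax, tree, params)))
        assert dbs[10] <= dbs[20]

    def test_matches_naive_reference_build(self, two_genus_fixture):
        """End-to-end equality with a pure-string pipeline on <= 5 kb genomes."""
        tree, genomes, seqtax = two_genus_fixture
        params = FWD
        db = build_database(genomes, seqtax, tree, params)

        # independent naive build: one string sweep per genome
        species_sets = {}
        for sid in sorted(genomes):
            sp = seqtax[sid]
            g = genomes[sid]
            species_sets.setdefault(sp, {})
            for i in range(len(g) - 31):
                key = (g[i : i + params.codec.n], g[i + 16 : i + 32])
                species_sets[sp].setdefault(key, []).append(i)
        merged = {}
        by_genus = {}
        for sp in sorted(species_sets):
            by_genus.setdefault(tree.ancestor_at_rank(sp, "genus"), []).append(sp)
        stride = params.stride
        for genus, sps in sorted(by_genus.items()):
            counts = {}
            for sp in sps:
                for key in species_sets[sp]:
                    counts.setdefault(key, []).append(sp)
            for key, present in counts.items():
                taxid = genus if len(present) >= 2 else present[0]
                if taxid == genus:
                    keep = True
                else:
                    pos = species_sets[present[0]][key]
                    keep = any(p % stride == 0 for p in pos)
                if keep:
                    merged.setdefault(key, set()).add(taxid)
        expected = {
            key: next(iter(t)) for key, t in merged.items() if len(t) == 1
        }

        got = {}
        from dktax.codec import decode_bases

        sizes = db.group_size
        for gid in np.nonzero(sizes)[0]:
            lo = int(db.offsets[gid])
            for j in range(lo, lo + int(sizes[gid])):
                key = (decode_bases(int(gid), params.codec.n),
                       decode_bases(int(db.suffixes[j]), 16))
                got[key] = int(db.taxids[j])
        assert got == expected


class TestSerialization:
    def test_round_trip_equality(self, two_genus_fixture, tmp_path):
        tree, genomes, seqtax = two_genus_fixture
        db = build_database(genomes, seqtax, tree, P10)
        write_database(db, str(tmp_path / "db"))
        loaded = read_database(str(tmp_path / "db"))
        assert loaded == db
        assert loaded.tree is not None and 100 in loaded.tree

    def test_truncated_suffix_file(self, two_genus_fixture, tmp_path):
        tree, genomes, seqtax = two_genus_fixture
        db = build_database(genomes, seqtax, tree, P10)
        out = tmp_path / "db"
        write_database(db, str(out))
        data = (out / "suffix.bin").read_bytes()
        (out / "suffix.bin").write_bytes(data[:-8])
        with pytest.raises(FormatError):
            read_database(str(out))

    def test_header_group_count_mismatch(self, two_genus_fixture, tmp_path):
        import json

        tree, genomes, seqtax = two_genus_fixture
        db = build_database(genomes, seqtax, tree, P10)
        out = tmp_path / "db"
        write_database(db, str(out))
        header = json.loads((out / "header.json").read_text())
        header["n"] = 11  # size.bin no longer holds 4^n entries
        (out / "header.json").write_text(json.dumps(header))
        with pytest.raises(FormatError):
            read_database(str(out))

    def test_bad_magic(self, two_genus_fixture, tmp_path):
        import json

        tree, genomes, seqtax = two_genus_fixture
        db = build_database(genomes, seqtax, tree, P10)
        out = tmp_path / "db"
        write_database(db, str(out))
        header = json.loads((out / "header.json").read_text())
        header["magic"] = "NOTADB"
        (out / "header.json").write_text(json.dumps(header))
        with pytest.raises(FormatError):
            read_database(str(out))
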