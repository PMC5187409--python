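import numpy as np
import pandas as pd
import pytest

from mitodyn.screen import (
    READ_PREFIX,
    VECTOR_SUFFIX,
    Library,
    call_hits,
    count_inserts,
    extract_insert,
    extract_inserts_from_fastq,
)
from mitodyn.synthetic import simulate_screen_reads, write_fastq
from mitodyn.validation import brute_force_hits, random_count_table

INSERT = "ACGTACGTACGTACGTACGTA"
GOOD_READ = READ_PREFIX + INSERT + VECTOR_SUFFIX + "ACGTACGT"
Q40 = chr(40 + 33) * len(GOOD_READ)


class TestExtractInsert:
    def test_valid_read_yields_its_insert(self):
        assert extract_insert(GOOD_READ, Q40) == INSERT

    def test_single_low_quality_base_in_pattern_rejects(self):
        quals = [40] * len(GOOD_READ)
        quals[12] = 34  # inside the matched 50-nt region
        assert extract_insert(GOOD_READ, quals) is None

    def test_low_quality_in_tail_is_ignored(self):
        quals = [40] * len(GOOD_READ)
        quals[55] = 2  # beyond the matched region
        assert extract_insert(GOOD_READ, quals) == INSERT

    @pytest.mark.parametrize(
        "read",
        [
            "A" + GOOD_READ[1:],                     # wrong prefix
            GOOD_READ[:30],                          # too short
            GOOD_READ[:26] + "T" + GOOD_READ[27:],   # corrupted vector sequence
        ],
        ids=["prefix", "short", "suffix"],
    )
    def test_pattern_violations_reject(self, read):
        assert extract_insert(read, chr(73) * len(read)) is None


class TestCounting:
    def test_exact_match_counts_and_conservation(self, toy_library):
        seqs = toy_library.records["sequence21"].tolist()
        inserts = {"exp1": [seqs[0]] * 3 + [seqs[1]] * 2 + ["A" * 21], "exp2": [seqs[0]]}
        counts = count_inserts(inserts, toy_library)
        assert counts.counts.loc["sh0_0", "exp1"] == 3
        assert counts.counts.loc["sh0_1", "exp1"] == 2
        assert counts.unmapped["exp1"] == 1
        # conservation: mapped + unmapped = accepted inserts
        for rep, ins in inserts.items():
            assert counts.counts[rep].sum() + counts.unmapped[rep] == len(ins)

    def test_hamming_one_insert_unmapped_under_exact_policy(self, toy_library):
        seq = toy_library.records["sequence21"].iloc[0]
        mutated = ("A" if seq[0] != "A" else "C") + seq[1:]
        counts = count_inserts({"exp1": [mutated], "exp2": []}, toy_library)
        assert counts.unmapped["exp1"] == 1
        tolerant = count_inserts(
            {"exp1": [mutated], "exp2": []}, toy_library, allow_one_mismatch=True
        )
        assert tolerant.counts.loc["sh0_0", "exp1"] == 1

    def test_duplicate_library_sequences_rejected(self):
        lib = pd.DataFrame(
            {
                "shrna_id": ["a", "b"],
                "gene": ["G1", "G2"],
                "sequence21": ["A" * 21, "A" * 21],
            }
        )
        with pytest.raises(ValueError):
            count_inserts({"exp1": [], "exp2": []}, Library(lib))


class TestHitCalling:
    def _counts(self, per_gene, replicates=("exp1", "exp2")):
        rows, idx = [], []
        for gene, reads in per_gene.items():
            for i, r in enumerate(reads):
                idx.append(f"{gene}_{i}")
                rows.append(r if isinstance(r, tuple) else (r, r))
        table = pd.DataFrame(rows, columns=list(replicates), index=pd.Index(idx, name="shrna_id"))
        lib = Library(
            pd.DataFrame(
                {
                    "shrna_id": idx,
                    "gene": [i.rsplit("_", 1)[0] for i in idx],
                    "sequence21": [
                        "".join(np.random.default_rng(k).choice(list("ACGT"), 21))
                        for k in range(len(idx))
                    ],
                }
            )
        )
        return table, lib

    def test_three_shrnas_over_500_in_both_replicates_is_a_hit(self):
        table, lib = self._counts({"GENEA": [600, 501, 700, 10, 0]})
        hits = call_hits(table, lib)
        assert bool(hits.loc[hits["gene"] == "GENEA", "is_hit"].iloc[0])

    def test_499_reads_is_below_the_at_least_500_boundary(self):
        table, lib = self._counts({"GENEA": [600, 600, 499, 0, 0]})
        hits = call_hits(table, lib)
        assert not bool(hits.loc[hits["gene"] == "GENEA", "is_hit"].iloc[0])

    def test_significance_in_one_experiment_only_is_not_a_hit(self):
        table, lib = self._counts(
            {"GENEA": [(600, 10), (600, 10), (600, 10)]}
        )
        hits = call_hits(table, lib)
        row = hits.loc[hits["gene"] == "GENEA"].iloc[0]
        assert bool(row["significant_exp1"]) and not bool(row["significant_exp2"])
        assert not bool(row["is_hit"])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        counts, gene_of, lib = random_count_table(rng, n_genes=30)
        got = set(call_hits(counts, lib).query("is_hit")["gene"])
        assert got == brute_force_hits(counts, gene_of)

    def test_tightening_thresholds_never_adds_hits(self):
        rng = np.random.default_rng(99)
        counts, _gene_of, lib = random_count_table(rng)
        base = set(call_hits(counts, lib, min_reads=500, min_shrnas=3).query("is_hit")["gene"])
        for mr, ms in [(600, 3), (500, 4), (800, 5)]:
            tighter = set(
                call_hits(counts, lib, min_reads=mr, min_shrnas=ms).query("is_hit")["gene"]
            )
            assert tighter <= base


class TestEndToEnd:
    def test_error_free_reads_reproduce_truth_counts(self, toy_library, tmp_path):
        rng = np.random.default_rng(8)
        abundances = {
            sid: int(rng.integers(0, 40)) for sid in toy_library.records["shrna_id"]
        }
        reads, truth = simulate_screen_reads(toy_library, abundances, error_rate=0.0, seed=4)
        fq = tmp_path / "exp1.fastq"
        write_fastq(reads, fq)
        inserts, rejected = extract_inserts_from_fastq(fq)
        assert rejected == 0
        counts = count_inserts({"exp1": inserts, "exp2": []}, toy_library)
        for sid, n in truth.items():
            assert counts.counts.loc[sid, "exp1"] == n
        assert counts.unmapped["exp1"] == 0

    def test_substitution_errors_become_unmapped(self, toy_library, tmp_path):
        abundances = {toy_library.records["shrna_id"].iloc[0]: 10_000}
        reads, truth = simulate_screen_reads(
            toy_library, abundances, error_rate=0.1, seed=4
        )
        fq = tmp_path / "exp1.fastq"
        write_fastq(reads, fq)
        inserts, _rej = extract_inserts_from_fastq(fq)
        counts = count_inserts({"exp1": inserts, "exp2": []}, toy_library)
        mapped = counts.counts["exp1"].sum()
        # binomial expectation: ~90% of reads map back exactly
        assert mapped == sum(truth.values())
        assert mapped / len(reads) == pytest.approx(0.9, abs=0.01)
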