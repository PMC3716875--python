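# structscan

Semi-global scanning of long RNA targets for occurrences of a
structure-annotated query, scoring sequence and thermodynamic-structure
evidence jointly.

The target is annotated with (sparse, span-limited) base-pair probabilities —
read from a triplet text file or computed by a built-in simplified windowed
partition-function folder.  The query is a single sequence or a multiple
alignment with a consensus dot-bracket structure; its structure pairs enter
as probability-1 base pairs and its residues as per-column log-odds profiles.
A banded dynamic program evaluates simultaneous alignment-and-base-pair-match
scores in one left-to-right pass with memory bounded by (span x query
length), independent of the target length.  Locally-maximal scores are
pruned online for domination, the best K are kept, left ends and full
alignments are recovered by bounded recomputation, and significance is
calibrated from an affine fit to the tail of the empirical score
distribution.

## Layout

| module | contents |
|---|---|
| `structscan.model` | domain types (sequences, bpp matrices, profiles, alignments) and the scoring functions sigma/tau/psi, gap model, total score |
| `structscan.scan` | the banded DP engine (rotating S* band, per-right-end S slices, sparse D store) |
| `structscan.report` | local maxima, online domination pruning, top-K queue, score histogram, affine tail fit / e-values |
| `structscan.traceback` | occurrence length bound, bounded region recomputation, deterministic traceback |
| `structscan.fold` | bpp file I/O, windowed Nussinov–Boltzmann inside–outside folder (optional no-lonely-pairs helix grammar and helix-initiation cost), single-structure probabilities, constrained MFE folding |
| `structscan.decoys` | cloverleaf templates, inverse-folded (stabilized) and complement-sampled (non-stabilized) decoys, pseudogenome assembly, overlap classification |
| `structscan.cli` | `structscan` command-line front end and the benchmark pipeline |

Scores are integers in hundredths of natural-log units.  Coordinates are
1-based inclusive everywhere except BED output.

## CLI

```sh
# fold a target: windowed pair probabilities (TSV: i, j, p)
structscan fold target.fa -o target.bpp --window 200 --span 100 --floor 0.5

# scan with a query (plain: sequence line + dot-bracket line; or
# Stockholm/Clustal alignment with SS_cons / --structure)
structscan scan target.fa query.txt --bpp target.bpp -o hits.tsv --bed hits.bed

# synthetic decoy set / full benchmark
structscan decoys --seed 1 -o decoy_out/
structscan benchmark --seed 1 -o bench_out/
```

Scan defaults mirror the published parameterization: struct-weight 200,
tau 400, indel -100, indel-opening -500, log-odds sequence scoring on.
Options may also be given via `--config file.yaml` (explicit command-line
flags win).

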