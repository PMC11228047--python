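# holotag

Hologenome analysis from type IIB restriction tags. A type IIB enzyme (the
shipped default is BsaXI, `AC(N5)CTCC`, 33 bp tags) excises one fixed-length
fragment per recognition site; because host and microbial DNA are sequenced
together in one library, those tags can simultaneously genotype the host and
profile its microbiome — provided a database first separates host-unique tags
from microbial taxon-specific markers.

The package covers the whole computational workflow:

* **enzyme** — IUPAC pattern matching, double-strand in-silico digestion,
  strand-normalized (canonical) tag keys.
* **database** — host tag sets (distinct vs genome-wide single-copy),
  rank-specific single-copy microbial markers, the host/microbe
  cross-redundancy removal with its impact report, TSV+JSON serialization.
* **qc** — the three read filters (any N; homopolymer run > 10 bp; > 20% of
  bases below Q10) and sequenced-tag extraction from Phred+33 FASTQ.
* **classify** — exact (optionally mismatch-tolerant) tag partitioning into
  host / species / unassigned with mapping rates over assigned tags, and
  marker-density relative-abundance profiles with a G-score
  (`sqrt(reads x markers_hit)`) false-positive filter.
* **genotype** — mismatch-tolerant pileups onto reference host tags, a
  binomial maximum-likelihood diploid caller (reliable depth >= 5, i.e.
  "coverage greater than 4x"), replicate-agreement reports stratified by
  call class, and allele-sharing distance matrices.
* **diversity** — Shannon (natural log) / Simpson, Bray–Curtis, classical
  PCoA, and Saitou–Nei neighbor joining with Newick output.
* **simulate** — fully specified synthetic holobiomes: planted restriction
  sites, diploid host SNPs, known community composition, deliberate tag
  sharing, and error-bearing reads whose ids carry their source labels, so
  every stage has an exact recovery oracle.

## CLI

Everything is wired through one entry point:

```sh
# make a synthetic experiment (genomes, taxonomy, truth, 2 FASTQ libraries)
holotag simulate --seed 7 --samples 2 -o exp/

# build the merged database
holotag build-db --host exp/host.fa --microbes exp/microbes/ \
    --taxonomy exp/taxonomy.tsv --enzyme BsaXI --rank species -o db/

# per-sample stages
holotag qc -i exp/sample1.fq -o s1.tags.tsv --stats s1.stats.json
holotag classify --db db/ --tags s1.tags.tsv -o s1
holotag profile --db db/ --assignments s1.assignments.tsv -o s1.profile.tsv
holotag genotype --db db/ --tags s1.tags.tsv -o s1.genotypes.tsv

# cross-sample reports
holotag agreement s1.genotypes.tsv s2.genotypes.tsv -o agreement.tsv
holotag gdist s1.genotypes.tsv s2.genotypes.tsv -o dist.phylip
holotag njtree dist.phylip -o tree.nwk
holotag diversity s1.profile.tsv s2.profile.tsv -o diversity.tsv
holotag pcoa s1.profile.tsv s2.profile.tsv -o ordination

# or the whole pipeline from a YAML config
holotag run-all --config run.yaml -o bundle/
```

`run.yaml` names the database directory, the samples, and thresholds
(`max_mismatch`, `min_markers`, `min_g_score`, `error_rate`, `min_depth`).
Reports are TSV with a JSON sidecar (config hash, seed, per-stage counts);
reruns are byte-identical.

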