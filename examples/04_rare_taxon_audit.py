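"""Audit a low-abundance taxon call with paired-read concordance.

A pathogen call resting on a handful of single-mate alignments is weak:
spurious hits rarely land on both mates of a pair, and rarely survive a
second, independent classifier. This fixture plants 47 reads on one taxon
across 16 samples, of which only 5 pairs are concordant and only 1 read is
confirmed by the second classifier.
"""

import json

from plasmeta.pairs import concordance_report, pair_concordance
from plasmeta.simulate import make_rare_taxon_tables

assignments, second_classifier = make_rare_taxon_tables(
    taxon="Borrelia", total_reads=47, concordant_pairs=5,
    confirmed_reads=1, n_samples=16, seed=0,
)

stats = pair_concordance(assignments, "Borrelia", second_classifier)
report = concordance_report(stats, total_samples=102)

print(f"reads assigned to the taxon:   {stats.total_reads}")
print(f"concordant mate pairs:         {stats.concordant_pairs}")
print(f"confirmed by 2nd classifier:   {stats.confirmed_reads}")
print(f"verdict: {report['verdict']}")
print("thresholds:", json.dumps(report["thresholds"]))
# 5 concordant pairs across 102 samples and a 2% confirmation rate fall far
# below the support thresholds, so the presence call is judged unsupported.
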