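"""Traditional cluster analysis: thematic lists and phonematic rules.

A semantic-task word sequence is clustered by shared category lists
(parrot bridges pets and birds), and a phonematic sequence by the four
Troyer rules.  Cluster size = words in cluster minus 1; switches =
number of clusters minus 1.
"""

from vftclust import (
    CategoryLexicon,
    cluster_metrics,
    identify_list_clusters,
    identify_rule_clusters,
    rule_match,
    Transcript,
    WordToken,
)

lex = CategoryLexicon({
    "dog": {"pets"}, "cat": {"pets"}, "parrot": {"pets", "birds"},
    "eagle": {"birds"}, "lion": {"africa"}, "giraffe": {"africa"},
})

words = ["dog", "cat", "parrot", "eagle", "lion", "giraffe"]
clustering = identify_list_clusters(words, lex)
print("semantic clusters:",
      [words[c.start:c.end] for c in clustering.clusters])
tr = Transcript(task="semantic", cue="animals",
                tokens=tuple(WordToken(w) for w in words))
m = cluster_metrics(tr, clustering)
print(f"total={m.total_word_count} mean_cluster_size={m.mean_cluster_size:.2f} "
      f"switches={m.switches}")
# dog-cat-parrot-eagle chain through shared lists into one 4-word cluster
# (size 3); lion-giraffe form a second cluster (size 1): 1 switch.

phon = ["simple", "simulate", "silly", "sand", "stand", "tiger"]
clustering = identify_rule_clusters(phon)
print("phonematic clusters:",
      [phon[c.start:c.end] for c in clustering.clusters])
print("sand/stand matched by:", sorted(rule_match("sand", "stand")))
# simple-simulate-silly share their first two letters; sand/stand rhyme;
# tiger matches nothing and stays a singleton.
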