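"""Chain vs feed-forward-loop classification of predicted motifs.

A method that cannot tell direct from transitively induced interactions
will report X->Y->Z chains as loops (adding the X->Z shortcut) or vice
versa; the classification counts those confusions against the reference.
"""

from grnimpact import classify_motifs

reference = {("A", "B"), ("B", "C"),            # chain A->B->C
             ("D", "E"), ("E", "F"), ("D", "F")}  # loop  D->E->F

predicted = {("A", "B"), ("B", "C"), ("A", "C"),  # spurious shortcut added
             ("D", "E"), ("E", "F")}              # shortcut missed

mc = classify_motifs(predicted, reference)
print(f"TP chains: {mc.n_tp} (chain in both networks)")
print(f"FP chains: {mc.n_fp} (predicted chain, actually a loop) -> "
      "a real shortcut was missed")
print(f"FN chains: {mc.n_fn} (predicted loop, actually a chain) -> "
      "a transitive edge was invented")
print(f"TPR = {mc.tpr}, FDR = {mc.fdr}")
print("ideal reconstruction keeps TPR near 1 and FDR near 0")
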