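# Toy haplogroup tree, rCRS-rooted (the rCRS is an H2a2a lineage, so the
# path "up" to the human root and "down" to C1b is a chain of rCRS-relative
# motifs).  The chain motifs are the lineage-defining assignments of the
# mummy fixture's non-private variants; the H1 branch and the sub-clades
# below C1b carry illustrative placeholder motifs used by classification,
# sister-clade and contamination tests.  Full-scale trees in the same format
# can be loaded with load_tree().
rCRS
 H2a2 263 8860 15326
  H2a 750
   H2 4769
    H 1438
     H1 3010
     HV 2706 7028
      R0 14766
       R 73 11719
        N 12705 16223
         L3 8701 9540 10398 10873 15301
          M 489 10400 14783 15043
           M8 4715 7196A 8584 15487T 16298
            CZ 249d
             C 3552A 9545 11914 13263 14318 16327
              C1 290-291d 16325
               C1b 493
                C1b2 16051 16292
                C1b6 9449 16093
                C1b13 12378
                 C1b13d 16104
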