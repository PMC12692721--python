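* SYNTHETIC stand-in property scales. The accession names below are
* placeholders for real physicochemical scales whose numeric values are
* NOT reproduced here; every value in this file is synthetic, drawn from
* a seeded normal distribution, and is intended only for exercising the
* descriptor machinery in examples and tests.
H KARS160108
D SYNTHETIC stand-in values (average weighted degree (network connectivity))
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.898   0.331  -0.501   0.348  -0.822   0.020  -0.038  -0.954   0.465  -1.421
  -1.533  -0.474  -0.469   1.256  -0.513   1.491  -0.106  -0.402   0.563  -0.043
//
H MUNV940102
D SYNTHETIC stand-in values (free energy in alpha-helical region)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.436   0.512   1.550   0.426  -0.165   1.589  -0.517   0.773  -0.886  -0.109
  -0.890   0.187  -0.335   1.009  -0.845  -0.737  -1.263   0.126  -1.488   1.957
//
H MUNV940103
D SYNTHETIC stand-in values (free energy in beta-strand conformation)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   1.104   0.632  -1.271  -1.065   1.776   0.628  -1.251   0.166   0.169   1.894
  -0.157   0.276  -0.039  -0.687   0.106  -0.887  -0.898  -0.482   0.732  -1.210
//
H MIYS990102
D SYNTHETIC stand-in values (optimized relative partition energies, method A)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -2.054  -0.454  -0.418   0.429  -0.265  -0.438  -2.197   0.666  -0.166   2.450
  -0.801   1.050   2.543  -0.786   0.285   0.339  -0.540   0.851   0.837   2.789
//
H PTIO830101
D SYNTHETIC stand-in values (helix-coil equilibrium constant)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.453  -0.731   1.381  -0.817  -0.632   1.167  -0.624  -1.293   0.513  -0.016
  -0.042  -0.390  -0.982  -1.934   1.133  -0.558   0.104   0.412  -0.503  -1.600
//
H PONP800104
D SYNTHETIC stand-in values (surrounding hydrophobicity in alpha-helix)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.636   0.205  -0.449   1.086  -0.006  -0.416  -2.324   0.551  -0.925  -0.563
   1.088  -0.201   0.849   0.981   0.290  -0.688   0.127  -1.163   0.395  -1.736
//
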