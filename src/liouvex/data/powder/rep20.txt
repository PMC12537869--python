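  346.084276   154.685855 0.0500000000
  223.813064   152.184699 0.0500000000
   90.630772   144.996018 0.0500000000
  296.820976   118.722256 0.0500000000
  157.934733   127.948842 0.0500000000
   37.847897   117.684716 0.0500000000
  246.005558   108.728961 0.0500000000
  111.270412   101.449580 0.0500000000
  345.247437   105.369379 0.0500000000
  198.549482    97.984374 0.0500000000
   68.814071    82.055007 0.0500000000
  282.086284    74.480517 0.0500000000
  156.020943    78.738855 0.0500000000
   21.387474    71.211124 0.0500000000
  229.445317    62.298571 0.0500000000
  109.490996    52.205884 0.0500000000
  330.554369    61.102518 0.0500000000
  176.570544    35.171864 0.0500000000
   43.880135    27.813437 0.0500000000
  281.053507    25.145847 0.0500000000
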