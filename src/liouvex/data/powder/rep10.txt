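   11.619317   150.908405 0.1000000000
  223.994451   141.136196 0.1000000000
  107.649763   122.198020 0.1000000000
  312.357710   101.872344 0.1000000000
  170.703039    92.003001 0.1000000000
   31.379891    87.731321 0.1000000000
  249.809834    78.762185 0.1000000000
   94.407489    57.076723 0.1000000000
  337.342840    39.281109 0.1000000000
  191.813232    29.075865 0.1000000000
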