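  349.891081   156.444211 0.0333333333
  215.040072   161.119932 0.0333333333
   97.418104   154.243400 0.0333333333
  304.393326   129.059334 0.0333333333
  162.203073   129.755260 0.0333333333
   31.827283   126.691785 0.0333333333
  256.369267   129.816061 0.0333333333
  119.897463   116.881722 0.0333333333
  347.693784   113.560545 0.0333333333
  207.542232   120.471817 0.0333333333
   74.834223   118.615467 0.0333333333
  277.667496    94.270638 0.0333333333
  146.689822    89.037072 0.0333333333
   17.647983    89.222845 0.0333333333
  236.432463    94.739219 0.0333333333
   97.594352    85.564044 0.0333333333
  315.565306    90.726246 0.0333333333
  183.550737    90.645679 0.0333333333
   55.069507    85.615648 0.0333333333
  257.190022    60.678724 0.0333333333
  125.137049    57.663189 0.0333333333
  345.432707    66.491195 0.0333333333
  212.333411    65.085925 0.0333333333
   76.119157    51.220227 0.0333333333
  300.374889    54.117761 0.0333333333
  171.006703    49.800789 0.0333333333
   28.068167    50.101310 0.0333333333
  232.601859    26.233468 0.0333333333
  113.169747    17.984814 0.0333333333
  339.034661    24.002301 0.0333333333
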