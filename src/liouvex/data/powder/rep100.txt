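  338.176268   170.569009 0.0100000000
  227.307171   164.880958 0.0100000000
  115.624474   166.867840 0.0100000000
  295.461284   153.410846 0.0100000000
  168.963824   153.784392 0.0100000000
   38.878831   156.558373 0.0100000000
  255.061680   146.246940 0.0100000000
  121.398481   145.694484 0.0100000000
  344.760394   149.775561 0.0100000000
  212.875415   145.109542 0.0100000000
   81.939663   148.414410 0.0100000000
  288.247419   133.246883 0.0100000000
  150.014277   135.507779 0.0100000000
   15.720172   138.707819 0.0100000000
  233.054396   129.573778 0.0100000000
   99.671901   128.332481 0.0100000000
  318.936057   135.038894 0.0100000000
  185.363872   134.410999 0.0100000000
   47.340849   135.637965 0.0100000000
  262.315821   125.829505 0.0100000000
  124.649160   123.815651 0.0100000000
  345.871233   128.000419 0.0100000000
  208.422429   121.784560 0.0100000000
   73.253588   128.314052 0.0100000000
  307.239885   116.676511 0.0100000000
  167.268311   119.896057 0.0100000000
   32.560589   118.276768 0.0100000000
  244.600969   111.646717 0.0100000000
  104.020657   107.554627 0.0100000000
  329.905102   112.087681 0.0100000000
  188.398811   110.937837 0.0100000000
   56.348160   113.040384 0.0100000000
  282.164631   112.525402 0.0100000000
  145.396471   112.681134 0.0100000000
    8.677219   118.927715 0.0100000000
  223.728740   105.942670 0.0100000000
   81.407156   109.224399 0.0100000000
  317.968952    94.021277 0.0100000000
  166.894640    99.402709 0.0100000000
   40.339871    98.456853 0.0100000000
  263.381468   101.760593 0.0100000000
  125.163573   102.547478 0.0100000000
  352.135405   105.338501 0.0100000000
  204.888739    96.985966 0.0100000000
   65.226607    93.983888 0.0100000000
  297.832706    98.084522 0.0100000000
  146.807003    91.774162 0.0100000000
   17.282600   100.039131 0.0100000000
  241.641860    90.889280 0.0100000000
   88.517429    89.911920 0.0100000000
  338.173384    90.122523 0.0100000000
  185.219387    89.130916 0.0100000000
   49.364709    80.061098 0.0100000000
  279.969227    88.061437 0.0100000000
  128.872217    81.850138 0.0100000000
    1.440748    86.070662 0.0100000000
  221.931203    83.213022 0.0100000000
   74.552080    74.729497 0.0100000000
  301.509284    77.343850 0.0100000000
  163.504128    78.129871 0.0100000000
   26.294313    81.629732 0.0100000000
  259.847811    80.466965 0.0100000000
  108.715770    85.932856 0.0100000000
  345.262032    70.811025 0.0100000000
  203.184798    74.202165 0.0100000000
   57.988290    61.186703 0.0100000000
  281.215805    67.132987 0.0100000000
  144.596163    67.448927 0.0100000000
   10.309836    67.015729 0.0100000000
  238.201439    69.081238 0.0100000000
   96.784975    67.912068 0.0100000000
  322.661266    72.424895 0.0100000000
  182.383847    68.364715 0.0100000000
   34.114369    61.833056 0.0100000000
  259.245792    59.978720 0.0100000000
  119.479040    63.273956 0.0100000000
  353.399741    51.726219 0.0100000000
  218.219163    58.218027 0.0100000000
   80.758939    52.076472 0.0100000000
  301.999054    56.083739 0.0100000000
  164.501129    54.228040 0.0100000000
   19.319553    44.479578 0.0100000000
  241.126139    45.504881 0.0100000000
  107.706264    44.973493 0.0100000000
  326.993665    51.655665 0.0100000000
  193.673565    50.378239 0.0100000000
   50.882975    41.421697 0.0100000000
  276.543355    44.356275 0.0100000000
  138.504061    46.746420 0.0100000000
  344.789424    31.614784 0.0100000000
  213.640012    34.755325 0.0100000000
   81.736894    30.345863 0.0100000000
  305.287486    34.232990 0.0100000000
  171.436728    33.765644 0.0100000000
   27.789955    23.581742 0.0100000000
  257.584932    26.082376 0.0100000000
  130.967998    26.603760 0.0100000000
  311.420325    13.078965 0.0100000000
  198.757779    15.007920 0.0100000000
   87.760650     9.565885 0.0100000000
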