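   26.591093   161.617731 0.0151515152
  233.641908   170.797313 0.0151515152
  114.674821   157.728680 0.0151515152
  316.134864   153.188959 0.0151515152
  172.017890   150.582789 0.0151515152
   33.949519   135.497290 0.0151515152
  263.428580   145.746201 0.0151515152
  120.558377   132.050811 0.0151515152
  351.621843   137.854747 0.0151515152
  217.543957   142.114637 0.0151515152
   72.685739   142.821974 0.0151515152
  295.304059   130.444560 0.0151515152
  153.794343   128.522707 0.0151515152
    9.691159   117.543953 0.0151515152
  244.259767   123.923760 0.0151515152
   91.718169   121.592301 0.0151515152
  324.058157   121.517040 0.0151515152
  188.703217   125.532176 0.0151515152
   61.360251   117.021604 0.0151515152
  271.899075   114.260546 0.0151515152
  136.806810   107.346991 0.0151515152
  345.149327   105.519666 0.0151515152
  218.173058   113.347080 0.0151515152
   81.796381    97.154296 0.0151515152
  298.262675   104.034263 0.0151515152
  167.506253   105.616725 0.0151515152
   35.429515   107.851091 0.0151515152
  248.505690    98.760608 0.0151515152
  111.103654   103.341833 0.0151515152
  322.036651    93.094544 0.0151515152
  195.255193   100.377802 0.0151515152
   56.924126    89.682675 0.0151515152
  273.679987    88.016226 0.0151515152
  150.259708    85.261336 0.0151515152
    8.553489    91.666058 0.0151515152
  225.550599    88.290535 0.0151515152
   99.995906    79.260593 0.0151515152
  298.290679    77.871976 0.0151515152
  176.855327    80.250552 0.0151515152
   32.208610    82.211618 0.0151515152
  250.162649    72.960257 0.0151515152
  125.732264    79.737545 0.0151515152
  345.850717    78.010471 0.0151515152
  203.182200    76.225095 0.0151515152
   73.295034    69.513864 0.0151515152
  277.677832    61.096971 0.0151515152
  158.395230    60.656900 0.0151515152
   11.432769    64.647928 0.0151515152
  224.384521    59.938334 0.0151515152
   98.651295    54.291360 0.0151515152
  321.461854    65.985131 0.0151515152
  189.538416    53.625017 0.0151515152
   45.400084    60.819830 0.0151515152
  252.497947    46.234374 0.0151515152
  129.882495    54.488870 0.0151515152
  345.111417    49.978566 0.0151515152
  214.362459    33.864131 0.0151515152
   67.509190    41.677529 0.0151515152
  303.109323    45.469397 0.0151515152
  162.025424    34.532716 0.0151515152
   22.663219    40.540684 0.0151515152
  273.828995    24.678042 0.0151515152
  112.828406    29.375693 0.0151515152
  336.212233    25.368053 0.0151515152
  187.902979     9.214685 0.0151515152
   47.980007    17.263779 0.0151515152
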