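"""Built-in Gaussian basis-set tables.

Standard published contractions (STO-3G: Hehre, Stewart, Pople, JCP 51, 2657;
6-31G: Hehre, Ditchfield, Pople, JCP 56, 2257, and later extensions), stored as
{basis: {element: [[l, [exp, coef], ...], ...]}}.
"""

BASIS_TABLES = {"sto-3g": {"H": [[0, [3.42525091, 0.15432897], [0.62391373, 0.53532814], [0.1688554, 0.44463454]]], "He": [[0, [6.36242139, 0.15432897], [1.158923, 0.53532814], [0.31364979, 0.44463454]]], "C": [[0, [71.616837, 0.15432897], [13.045096, 0.53532814], [3.5305122, 0.44463454]], [0, [2.9412494, -0.09996723], [0.6834831, 0.39951283], [0.2222899, 0.70011547]], [1, [2.9412494, 0.15591627], [0.6834831, 0.60768372], [0.2222899, 0.39195739]]], "N": [[0, [99.106169, 0.15432897], [18.052312, 0.53532814], [4.8856602, 0.44463454]], [0, [3.7804559, -0.09996723], [0.8784966, 0.39951283], [0.2857144, 0.70011547]], [1, [3.7804559, 0.15591627], [0.8784966, 0.60768372], [0.2857144, 0.39195739]]], "O": [[0, [130.70932, 0.15432897], [23.808861, 0.53532814], [6.4436083, 0.44463454]], [0, [5.0331513, -0.09996723], [1.1695961, 0.39951283], [0.380389, 0.70011547]], [1, [5.0331513, 0.15591627], [1.1695961, 0.60768372], [0.380389, 0.39195739]]], "F": [[0, [166.67913, 0.15432897], [30.360812, 0.53532814], [8.2168207, 0.44463454]], [0, [6.4648032, -0.09996723], [1.5022812, 0.39951283], [0.4885885, 0.70011547]], [1, [6.4648032, 0.15591627], [1.5022812, 0.60768372], [0.4885885, 0.39195739]]], "S": [[0, [533.1257359, 0.1543289673], [97.1095183, 0.5353281423], [26.28162542, 0.4446345422]], [0, [33.32975173, -0.09996722919], [7.745117521, 0.3995128261], [2.518952599, 0.7001154689]], [0, [2.029194274, -0.219620369], [0.5661400518, 0.2255954336], [0.2215833792, 0.900398426]], [1, [33.32975173, 0.155916275], [7.745117521, 0.6076837186], [2.518952599, 0.3919573931]], [1, [2.029194274, 0.01058760429], [0.5661400518, 0.5951670053], [0.2215833792, 0.462001012]]], "Cl": [[0, [601.3456136, 0.1543289673], [109.5358542, 0.5353281423], [29.64467686, 0.4446345422]], [0, [38.96041889, -0.09996722919], [9.053563477, 0.3995128261], [2.944499834, 0.7001154689]], [0, [2.129386495, -0.219620369], [0.5940934274, 0.2255954336], [0.232524141, 0.900398426]], [1, [38.96041889, 0.155916275], [9.053563477, 0.6076837186], [2.944499834, 0.3919573931]], [1, [2.129386495, 0.01058760429], [0.5940934274, 0.5951670053], [0.232524141, 0.462001012]]]}, "6-31g": {"H": [[0, [18.731137, 0.0334946], [2.8253937, 0.23472695], [0.6401217, 0.81375733]], [0, [0.1612778, 1.0]]], "He": [[0, [38.421634, 0.023766], [5.77803, 0.154679], [1.241774, 0.46963]], [0, [0.297964, 1.0]]], "C": [[0, [3047.5249, 0.0018347], [457.36951, 0.0140373], [103.94869, 0.0688426], [29.210155, 0.2321844], [9.286663, 0.4679413], [3.163927, 0.362312]], [0, [7.8682724, -0.1193324], [1.8812885, -0.1608542], [0.5442493, 1.1434564]], [0, [0.1687144, 1.0]], [1, [7.8682724, 0.0689991], [1.8812885, 0.316424], [0.5442493, 0.7443083]], [1, [0.1687144, 1.0]]], "N": [[0, [4173.511, 0.0018348], [627.4579, 0.013995], [142.9021, 0.068587], [40.23433, 0.232241], [12.82021, 0.46907], [4.390437, 0.360455]], [0, [11.626358, -0.114961], [2.71628, -0.169118], [0.772218, 1.145852]], [0, [0.2120313, 1.0]], [1, [11.626358, 0.06758], [2.71628, 0.323907], [0.772218, 0.740895]], [1, [0.2120313, 1.0]]], "O": [[0, [5484.6717, 0.0018311], [825.23495, 0.0139501], [188.04696, 0.0684451], [52.9645, 0.2327143], [16.89757, 0.470193], [5.7996353, 0.3585209]], [0, [15.539616, -0.1107775], [3.5999336, -0.1480263], [1.0137618, 1.130767]], [0, [0.2700058, 1.0]], [1, [15.539616, 0.0708743], [3.5999336, 0.3397528], [1.0137618, 0.7271586]], [1, [0.2700058, 1.0]]], "F": [[0, [7001.71309, 0.0018196169], [1051.36609, 0.0139160796], [239.28569, 0.0684053245], [67.3974453, 0.23318576], [21.5199573, 0.471267439], [7.4031013, 0.356618546]], [0, [20.8479528, -0.108506975], [4.80830834, -0.146451658], [1.34406986, 1.12868858]], [0, [0.358151393, 1.0]], [1, [20.8479528, 0.0716287243], [4.80830834, 0.345912103], [1.34406986, 0.722469957]], [1, [0.358151393, 1.0]]], "S": [[0, [21917.1, 0.001869], [3301.49, 0.01423], [754.146, 0.069696], [212.711, 0.238487], [67.9896, 0.483307], [23.0515, 0.338074]], [0, [423.735, -0.0023767], [100.71, -0.031693], [32.1599, -0.113317], [11.8079, 0.05609], [4.6311, 0.592255], [1.87025, 0.455006]], [0, [2.61584, -0.250374], [0.922167, 0.066957], [0.341287, 1.05451]], [0, [0.117167, 1.0]], [1, [423.735, 0.004061], [100.71, 0.030681], [32.1599, 0.130452], [11.8079, 0.327205], [4.6311, 0.452851], [1.87025, 0.256042]], [1, [2.61584, -0.014511], [0.922167, 0.310263], [0.341287, 0.754483]], [1, [0.117167, 1.0]]], "Cl": [[0, [25180.1, 0.001833], [3780.35, 0.014034], [860.474, 0.069097], [242.145, 0.237452], [77.3349, 0.483034], [26.247, 0.339856]], [0, [491.765, -0.0022974], [116.984, -0.030714], [37.4153, -0.112528], [13.7834, 0.045016], [5.45215, 0.589353], [2.22588, 0.465206]], [0, [3.18649, -0.25183], [1.14427, 0.061589], [0.420377, 1.06018]], [0, [0.142657, 1.0]], [1, [491.765, 0.0039894], [116.984, 0.030318], [37.4153, 0.12988], [13.7834, 0.327951], [5.45215, 0.453527], [2.22588, 0.252154]], [1, [3.18649, -0.014299], [1.14427, 0.323572], [0.420377, 0.743507]], [1, [0.142657, 1.0]]]}}
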