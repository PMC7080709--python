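# InChIKeys of common solvents removed during standardization.
# One key per line; text after the key is a comment (name).

XLYOFNOQVPJJNP-UHFFFAOYSA-N  water
OKKJLVBELUTLKV-UHFFFAOYSA-N  methanol
LFQSCWFLJHTTHZ-UHFFFAOYSA-N  ethanol
KFZMGEQAYNKOFK-UHFFFAOYSA-N  isopropanol
LRHPLDYGYMQRHN-UHFFFAOYSA-N  n-butanol
CSCPPACGZOOCGX-UHFFFAOYSA-N  acetone
IAZDPXIOMUYVGZ-UHFFFAOYSA-N  DMSO
ZMXDDKWLCZADIW-UHFFFAOYSA-N  DMF
WEVYAHXRMPXWCK-UHFFFAOYSA-N  acetonitrile
YMWUJEATGCHHMB-UHFFFAOYSA-N  dichloromethane
HEDRZPFGACZZDS-UHFFFAOYSA-N  chloroform
WYURNTSHIVDZCO-UHFFFAOYSA-N  THF
RYHBNJHYFVUHQT-UHFFFAOYSA-N  1,4-dioxane
RTZKZFJDLAIYFH-UHFFFAOYSA-N  diethyl ether
XEKOWRVHYACXOJ-UHFFFAOYSA-N  ethyl acetate
YXFVVABEGXRONW-UHFFFAOYSA-N  toluene
VLKZOEOYAKHREP-UHFFFAOYSA-N  n-hexane
QTBSBXVTEAMEQO-UHFFFAOYSA-N  acetic acid
BDAGIHXWWSANSR-UHFFFAOYSA-N  formic acid
JUJWROOIHBZHMG-UHFFFAOYSA-N  pyridine
SECXISVLQFMRJM-UHFFFAOYSA-N  NMP
LYCAIKOWRPUZTN-UHFFFAOYSA-N  ethylene glycol
PEDCQBHIVMGVHV-UHFFFAOYSA-N  glycerol
ZHNUHDYFZUAESO-UHFFFAOYSA-N  formamide
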