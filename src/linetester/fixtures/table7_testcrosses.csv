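line,tester,mean_yield,sca,sig,tester_grand_mean,se_mean,sca_se,note
TZEEI 60,TZEEI 63,1066,-48,ns,1199,101.0,174.5,
TZEEI 60,TZEEI 79,1373,-319,ns,1776,103.0,174.5,
TZEEI 60,TZEEI 95,3987,2316,p01,1756,104.0,174.5,
TZEEI 61,TZEEI 63,1111,-168,ns,1199,101.0,174.5,
TZEEI 61,TZEEI 79,1686,-170,ns,1776,103.0,174.5,
TZEEI 61,TZEEI 95,2434,598,p01,1756,104.0,174.5,
TZEEI 62,TZEEI 63,503,-446,ns,1199,101.0,174.5,
TZEEI 62,TZEEI 79,1486,-40,ns,1776,103.0,174.5,
TZEEI 62,TZEEI 95,1993,488,p01,1756,104.0,174.5,
TZEEI 69,TZEEI 63,1616,335,p05,1199,101.0,174.5,
TZEEI 69,TZEEI 79,1729,-130,ns,1776,103.0,174.5,
TZEEI 69,TZEEI 95,1636,-203,ns,1756,104.0,174.5,
TZEEI 71,TZEEI 63,922,-4188,p01,1199,101.0,174.5,sca_63_magnitude_as_printed
TZEEI 71,TZEEI 79,2253,336,p05,1776,103.0,174.5,
TZEEI 71,TZEEI 95,1981,84,ns,1756,104.0,174.5,
TZEEI 72,TZEEI 63,935,-93,ns,1199,101.0,174.5,
TZEEI 72,TZEEI 79,1948,342,p05,1776,103.0,174.5,
TZEEI 72,TZEEI 95,1338,-247,ns,1756,104.0,174.5,
TZEEI 74,TZEEI 63,728,-300,ns,1199,101.0,174.5,
TZEEI 74,TZEEI 79,2055,449,p01,1776,103.0,174.5,
TZEEI 74,TZEEI 95,1438,-148,ns,1756,104.0,174.5,
TZEEI 76,TZEEI 63,761,-385,p05,1199,101.0,174.5,
TZEEI 76,TZEEI 79,1960,236,ns,1776,103.0,174.5,
TZEEI 76,TZEEI 95,1853,151,ns,1756,104.0,174.5,
TZEEI 77,TZEEI 63,1337,418,p05,1199,101.0,174.5,
TZEEI 77,TZEEI 79,1311,-185,ns,1776,103.0,174.5,
TZEEI 77,TZEEI 95,1245,-231,ns,1756,104.0,174.5,
TZEEI 78,TZEEI 63,1446,357,p05,1199,101.0,174.5,
TZEEI 78,TZEEI 79,1501,-166,ns,1776,103.0,174.5,
TZEEI 78,TZEEI 95,1457,-189,ns,1756,104.0,174.5,
TZEEI 87,TZEEI 63,1652,506,p01,1199,101.0,174.5,
TZEEI 87,TZEEI 79,1419,-304,ns,1776,103.0,174.5,
TZEEI 87,TZEEI 95,1503,-200,ns,1756,104.0,174.5,
TZEEI 96,TZEEI 63,1664,473,p01,1199,101.0,174.5,
TZEEI 96,TZEEI 79,1037,-732,p01,1776,103.0,174.5,
TZEEI 96,TZEEI 95,2009,260,ns,1756,104.0,174.5,
TZEEI 97,TZEEI 63,1551,44,ns,1199,101.0,174.5,
TZEEI 97,TZEEI 79,2471,386,p05,1776,103.0,174.5,
TZEEI 97,TZEEI 95,1637,-428,p01,1756,104.0,174.5,
TZEEI 98,TZEEI 63,1982,561,p01,1199,101.0,174.5,
TZEEI 98,TZEEI 79,1756,-244,ns,1776,103.0,174.5,
TZEEI 98,TZEEI 95,1665,-315,ns,1756,104.0,174.5,
TZEEI 99,TZEEI 63,1826,632,p01,1199,101.0,174.5,
TZEEI 99,TZEEI 79,1512,-260,ns,1776,103.0,174.5,
TZEEI 99,TZEEI 95,1382,-370,p05,1756,104.0,174.5,
TZEEI 101,TZEEI 63,1743,409,p01,1199,101.0,174.5,
TZEEI 101,TZEEI 79,1908,-3,ns,1776,103.0,174.5,
TZEEI 101,TZEEI 95,1487,-404,p05,1756,104.0,174.5,
TZEEI 102,TZEEI 63,462,-578,p01,1199,101.0,174.5,
TZEEI 102,TZEEI 79,1516,-101,ns,1776,103.0,174.5,
TZEEI 102,TZEEI 95,2707,1110,p01,1756,104.0,174.5,
TZEEI 115,TZEEI 63,728,-375,p05,1199,101.0,174.5,
TZEEI 115,TZEEI 79,1833,152,ns,1776,103.0,174.5,
TZEEI 115,TZEEI 95,1885,225,ns,1756,104.0,174.5,
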