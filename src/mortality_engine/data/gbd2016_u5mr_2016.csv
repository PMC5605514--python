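country,stillbirth_rate,neonatal_rate,postneonatal_rate,child_1_4_rate,u5mr_2016,u5mr_roc_2000_2016_pct
Canada,2.0,3.1,1.5,0.7,5.4,-0.9
Greenland,5.6,7.7,3.7,2.8,14.1,-2.0
USA,2.8,3.9,1.9,1.0,6.8,-1.1
Australia,3.0,2.2,1.0,0.7,3.9,-3.1
New Zealand,3.3,3.1,1.6,0.9,5.6,-1.9
Brunei,2.6,4.3,3.4,1.5,9.2,0.2
Japan,1.7,0.9,1.0,0.7,2.6,-3.4
Singapore,1.9,1.0,0.8,0.5,2.3,-3.3
South Korea,1.9,1.5,1.2,0.8,3.5,-4.3
Andorra,2.7,1.2,0.7,1.5,3.3,0.3
Austria,1.8,1.9,0.9,0.6,3.4,-3.3
Belgium,1.8,2.0,1.2,0.8,3.9,-2.5
Cyprus,2.1,1.7,1.0,0.6,3.3,-5.7
Denmark,1.3,2.5,1.0,0.6,4.1,-2.0
Finland,1.1,1.2,0.6,0.4,2.2,-4.1
France,3.3,2.1,1.1,0.7,3.8,-2.2
Germany,1.5,1.9,1.1,0.6,3.6,-2.5
Greece,1.9,2.2,1.1,0.6,3.9,-3.0
Iceland,1.2,1.0,0.6,0.7,2.2,-3.8
Ireland,2.1,2.2,1.1,0.6,3.9,-3.9
Israel,2.4,1.8,1.1,0.7,3.6,-4.3
Italy,1.5,1.9,0.8,0.5,3.2,-3.2
Luxembourg,1.8,1.1,0.6,0.5,2.2,-4.8
Malta,2.5,4.4,1.1,0.7,6.3,-1.3
Netherlands,1.8,2.3,0.9,0.6,3.8,-3.2
Norway,1.5,1.5,0.7,0.5,2.7,-3.8
Portugal,1.6,1.5,0.9,0.6,3.1,-5.1
Spain,1.3,1.7,0.9,0.6,3.3,-3.0
Sweden,2.0,1.4,0.8,0.5,2.6,-2.5
Switzerland,1.7,2.6,0.8,0.5,3.9,-2.4
UK,3.5,2.6,1.3,0.7,4.6,-2.3
Argentina,5.4,6.9,3.6,1.8,12.2,-3.2
Chile,8.5,4.8,1.9,1.1,7.8,-2.1
Uruguay,4.6,4.5,3.0,1.3,8.8,-3.8
Belarus,2.8,2.7,1.6,1.3,5.5,-6.7
Estonia,1.5,1.3,1.0,0.8,3.1,-8.0
Latvia,2.3,2.5,1.4,0.9,4.8,-6.3
Lithuania,1.9,2.2,1.6,0.9,4.7,-5.5
Moldova,4.1,7.7,2.4,1.6,11.6,-6.2
Russia,2.8,4.2,2.5,1.7,8.4,-5.4
Ukraine,3.0,5.2,2.4,1.6,9.2,-5.1
Albania,4.1,7.2,4.2,2.3,13.7,-4.3
Bosnia and Herzegovina,3.6,3.5,0.9,0.8,5.2,-4.7
Bulgaria,3.9,4.0,2.9,1.5,8.3,-4.3
Croatia,2.3,2.8,1.0,0.7,4.5,-4.4
Czech Republic,1.7,1.4,0.9,0.5,2.8,-4.0
Hungary,2.4,3.0,1.8,0.8,5.6,-4.0
Macedonia,7.7,6.5,2.4,1.2,10.1,-2.2
Montenegro,3.3,3.0,1.4,0.7,5.1,-7.5
Poland,2.0,2.6,1.2,0.7,4.5,-4.7
Romania,3.9,4.5,3.4,1.5,9.5,-5.6
Serbia,4.7,4.5,2.3,1.1,7.9,-4.1
Slovakia,2.3,3.0,2.0,1.1,6.1,-3.1
Slovenia,1.9,1.5,0.4,0.5,2.4,-5.2
Armenia,6.8,6.1,4.1,1.9,12.1,-5.8
Azerbaijan,9.4,16.7,9.6,3.9,30.0,-4.6
Georgia,5.3,9.6,3.5,2.3,15.4,-5.6
Kazakhstan,5.2,6.6,4.2,2.7,13.5,-6.3
Kyrgyzstan,9.9,16.7,8.2,4.4,28.9,-3.4
Mongolia,7.1,11.2,6.1,4.1,21.2,-6.2
Tajikistan,8.9,16.9,14.1,7.1,37.6,-4.3
Turkmenistan,7.7,17.1,12.5,7.9,37.0,-4.9
Uzbekistan,7.1,12.0,7.2,4.5,23.5,-3.7
Colombia,8.5,9.0,3.6,3.0,15.5,-3.4
Costa Rica,5.9,6.5,2.6,1.5,10.6,-2.4
El Salvador,4.5,5.4,4.2,2.3,11.9,-5.6
Guatemala,6.6,10.8,9.7,6.5,26.7,-4.1
Honduras,8.4,11.6,5.5,4.4,21.4,-3.4
Mexico,4.0,7.3,5.4,2.8,15.5,-3.6
Nicaragua,5.4,7.4,4.9,2.8,15.1,-5.5
Panama,4.8,7.1,5.5,4.0,16.6,-2.1
Venezuela,5.6,10.0,4.3,2.6,16.8,-1.5
Bolivia,8.9,15.2,11.7,7.3,33.8,-4.8
Ecuador,5.3,8.2,5.3,3.9,17.3,-4.0
Peru,5.6,7.8,5.2,3.6,16.6,-5.2
Antigua and Barbuda,8.1,5.7,2.8,2.7,11.2,-2.4
The Bahamas,12.1,5.3,3.5,2.2,11.0,-1.5
Barbados,9.4,9.9,3.5,1.4,14.7,-1.2
Belize,9.6,8.3,4.0,2.8,15.1,-3.9
Bermuda,5.9,1.7,0.8,1.4,3.9,-0.7
Cuba,10.4,2.4,1.7,1.2,5.3,-3.1
Dominica,15.1,18.2,4.8,2.1,25.0,1.8
Dominican Republic,11.9,17.6,6.3,3.7,27.4,-1.9
Grenada,10.5,9.8,3.2,2.4,15.4,0.0
Guyana,12.0,16.4,5.7,3.0,24.9,-2.8
Haiti,22.4,22.1,21.3,13.0,55.4,-3.7
Jamaica,12.8,11.4,5.2,3.6,20.1,-1.3
Puerto Rico,5.5,4.4,1.6,0.6,6.6,-4.0
Saint Lucia,13.7,13.0,2.7,1.8,17.5,-0.2
Saint Vincent and the Grenadines,11.7,10.6,4.0,2.0,16.6,-2.1
Suriname,15.7,20.4,10.7,4.0,34.8,-1.7
Trinidad and Tobago,12.9,15.9,2.7,2.5,20.9,-1.7
Virgin Islands,6.2,5.9,2.0,1.2,9.1,-2.7
Brazil,5.3,8.7,5.9,2.4,16.9,-3.9
Paraguay,5.2,10.6,5.7,2.6,18.9,-2.7
China,5.5,5.9,3.5,2.4,11.8,-6.8
North Korea,7.0,12.9,8.5,5.0,26.2,-7.6
Taiwan (province of China),4.0,2.2,1.5,1.0,4.7,-3.8
Cambodia,10.8,15.7,11.5,5.0,31.9,-6.8
Indonesia,8.7,13.5,7.4,4.5,25.2,-4.8
Laos,15.8,25.9,23.9,9.5,58.2,-5.5
Malaysia,3.5,2.9,1.9,1.3,6.0,-2.8
Maldives,4.8,4.6,1.3,1.6,7.5,-8.9
Mauritius,7.7,8.8,3.4,1.8,13.9,-1.6
Myanmar,7.6,15.0,8.0,5.0,27.7,-6.9
Philippines,7.1,11.6,6.6,6.1,24.1,-3.0
Sri Lanka,3.7,4.0,1.6,1.2,6.8,-5.7
Seychelles,6.8,7.8,1.7,1.9,11.4,-1.0
Thailand,3.5,3.3,1.6,1.6,6.4,-5.6
Timor-Leste,13.1,15.1,13.8,6.7,35.3,-6.5
Vietnam,6.1,7.0,3.1,3.1,13.1,-4.7
American Samoa,4.5,3.8,3.0,1.8,8.5,-3.1
Federated States of Micronesia,8.2,9.0,4.8,3.6,17.3,-4.4
Fiji,12.3,17.0,11.8,9.4,37.8,1.3
Guam,9.9,7.4,4.6,1.8,13.7,1.2
Kiribati,16.7,19.8,16.3,13.1,48.4,-1.9
Marshall Islands,9.0,10.5,5.8,6.0,22.2,-3.7
Northern Mariana Islands,2.4,1.2,0.6,0.7,2.5,-3.8
Papua New Guinea,20.6,20.6,17.0,13.1,49.9,-2.5
Samoa,5.0,4.7,2.7,3.0,10.4,-2.6
Solomon Islands,12.0,12.4,7.5,5.8,25.5,-2.1
Tonga,8.7,9.9,5.0,3.7,18.6,-1.5
Vanuatu,12.9,14.5,10.5,6.9,31.6,-1.4
Afghanistan,15.7,25.9,24.0,18.3,66.6,-4.5
Algeria,12.2,10.9,5.0,2.4,18.2,-3.7
Bahrain,5.1,2.7,2.8,1.4,6.9,-3.6
Egypt,9.1,9.2,6.6,3.6,19.3,-5.1
Iran,7.2,10.9,4.3,2.7,17.8,-5.2
Iraq,11.3,14.6,8.2,5.9,28.5,-2.5
Jordan,6.5,10.1,4.1,3.1,17.2,-2.8
Kuwait,5.4,5.1,2.9,1.5,9.4,-1.9
Lebanon,5.9,4.9,3.0,1.6,9.5,-4.1
Libya,4.9,6.4,3.4,4.2,13.9,-4.1
Morocco,9.5,13.4,5.6,2.8,21.7,-4.6
Palestine,5.3,8.8,5.1,2.9,16.7,-3.0
Oman,6.4,4.2,2.3,1.5,8.0,-4.2
Qatar,4.5,4.8,2.8,1.8,9.4,-3.5
Saudi Arabia,6.8,3.4,2.0,1.2,6.6,-8.0
Sudan,18.1,26.6,20.4,15.8,61.6,-2.7
Syria,4.8,6.5,4.6,16.1,27.0,2.5
Tunisia,8.8,7.4,3.0,2.2,12.5,-4.7
Turkey,7.5,8.8,4.1,2.9,15.7,-5.9
United Arab Emirates,2.8,2.7,1.7,1.3,5.7,-3.8
Yemen,14.5,19.8,15.3,9.1,43.6,-4.4
Bangladesh,16.1,21.0,7.5,5.9,34.0,-5.8
Bhutan,14.1,19.8,8.0,5.4,32.9,-6.0
India,15.8,21.8,10.7,7.2,39.2,-4.7
Nepal,15.2,18.5,7.1,4.0,29.4,-6.3
Pakistan,25.9,31.8,12.6,9.9,53.4,-3.3
Botswana,5.8,7.2,3.3,4.5,14.9,-9.1
Lesotho,17.0,27.9,25.7,14.5,66.6,-2.5
Namibia,8.8,15.9,12.3,8.7,36.5,-3.5
South Africa,9.8,15.2,19.6,9.2,43.4,-3.5
Swaziland,7.8,15.9,23.6,10.5,49.2,-4.0
Zimbabwe,23.1,23.5,19.6,14.4,56.5,-2.0
Benin,15.7,25.1,22.3,26.6,72.2,-4.1
Burkina Faso,13.1,28.7,33.6,50.6,108.8,-3.1
Cameroon,17.1,27.2,27.9,35.7,88.1,-2.7
Cape Verde,7.4,8.9,5.0,3.3,17.0,-6.1
Chad,28.6,30.8,37.1,49.6,113.1,-3.0
Côte d'Ivoire,19.3,32.1,27.8,28.0,85.3,-3.0
The Gambia,21.0,21.3,12.2,16.0,48.7,-3.6
Ghana,15.4,23.4,13.5,16.2,52.3,-4.1
Guinea,16.8,32.1,29.1,39.6,97.5,-3.6
Guinea-Bissau,20.9,29.0,18.6,26.0,71.8,-4.9
Liberia,15.3,22.4,23.4,20.9,65.3,-6.0
Mali,28.9,38.0,34.3,49.6,117.1,-3.1
Mauritania,14.9,23.9,14.0,13.2,50.3,-3.8
Niger,20.2,26.3,29.2,56.6,108.2,-4.6
Nigeria,34.3,35.7,30.5,46.6,108.7,-3.3
São Tomé and Príncipe,9.1,12.8,9.8,8.1,30.4,-5.5
Senegal,14.2,20.1,13.9,16.2,49.4,-5.3
Sierra Leone,24.8,34.8,42.9,42.6,115.6,-3.9
Togo,18.4,25.1,19.6,25.9,69.0,-3.6
Burundi,16.1,27.3,27.4,28.4,80.8,-4.4
Comoros,19.0,26.4,16.8,10.4,52.6,-3.9
Djibouti,19.4,18.0,17.2,13.6,48.0,-4.7
Eritrea,13.9,17.7,16.4,18.0,51.2,-3.7
Ethiopia,11.6,18.8,13.4,11.9,43.4,-7.3
Kenya,18.2,18.0,15.0,11.1,43.4,-4.6
Madagascar,20.0,26.6,29.2,26.1,79.7,-2.4
Malawi,15.7,24.2,23.8,22.6,69.0,-5.5
Mozambique,19.6,24.6,30.6,22.9,76.1,-4.7
Rwanda,12.7,18.0,16.5,15.6,49.2,-7.2
Somalia,24.0,28.8,34.8,37.0,97.2,-2.9
South Sudan,43.4,30.7,34.6,31.3,93.5,-2.7
Tanzania,15.3,21.0,19.6,16.2,55.7,-5.0
Uganda,15.1,22.3,22.3,19.1,62.4,-4.8
Zambia,16.1,20.9,20.7,19.4,59.7,-5.4
Angola,18.3,18.1,18.6,18.7,54.5,-6.4
Central African Republic,42.2,39.5,46.7,50.4,130.5,-2.0
Congo (Brazzaville),17.7,18.9,16.2,18.7,52.8,-4.2
Democratic Republic of the Congo,22.9,24.9,27.7,30.1,80.5,-4.0
Equatorial Guinea,19.2,20.2,19.6,18.3,57.0,-5.9
Gabon,17.7,19.2,13.4,11.7,43.7,-2.9
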